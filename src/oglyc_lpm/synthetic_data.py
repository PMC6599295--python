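"""Synthetic site-table generator.

Emulates the statistical structure of the estimation data so the whole
pipeline runs with no external download: class-labeled residue windows
with position-specific amino-acid frequencies (defaults are the published
positional marginals for O-GlcNAc sites), the N-glycosylation sequon
constraint on the negative class (N at -2, no P at -1 after re-centering),
structural covariates (ASA with a point mass at zero and a right-skewed
positive part, Ramachandran-like phi/psi modes, secondary-structure and
turn-type categories), and an optional known linear effect vector so that
estimator-recovery tests have a ground truth.

Positions are sampled independently — only marginal frequencies are
emulated; real windows carry positional couplings the generator does not
reproduce.  A user-supplied joint sampler can replace the marginal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .encoding import encode
from .study_io import AMINO_ACIDS, SiteRecord, StructureAnnotation, StudyTable


@dataclass
class StructureModel:
    """Class-conditional structural covariate distribution."""

    p_asa_zero: float = 0.002
    asa_meanlog: float = 3.4           # ~30 A^2 median exposure
    asa_sdlog: float = 0.8
    #: (weight, phi_mean, psi_mean, sd) Ramachandran-like modes
    rama_modes: tuple = ((0.45, -63.0, -43.0, 15.0),
                        (0.40, -120.0, 135.0, 25.0),
                        (0.15, -90.0, 0.0, 30.0))
    ss_probs: Mapping[str, float] = field(default_factory=lambda: {
        "Helix": 0.25, "Strand": 0.20, "Loop": 0.25, "Beta Turn": 0.10,
        "Gamma Turn": 0.05, "Beta Hairpin": 0.05,
        "Beta Hairpin Strand": 0.05, "Beta Bridges": 0.05})
    turn_probs: Mapping[str, float] = field(default_factory=lambda: {
        "I": 0.08, "II": 0.05, "II´": 0.03, "IV": 0.08, "VIII": 0.03,
        "Inverse": 0.03})

    def __post_init__(self):
        if not 0.0 <= self.p_asa_zero <= 1.0:
            raise ValueError("p_asa_zero must be in [0, 1]")


@dataclass
class GeneratorConfig:
    n_pos: int = 987
    n_neg: int = 1083
    half_width: int = 8
    s_fraction: float = 0.5912
    #: residue x offset percentage tables per class; None -> defaults
    residue_probs: Mapping[str, pd.DataFrame] | None = None
    structure_pos: StructureModel = field(default_factory=StructureModel)
    structure_neg: StructureModel = field(
        default_factory=lambda: StructureModel(
            p_asa_zero=0.0, asa_meanlog=3.8,
            rama_modes=((0.30, -63.0, -43.0, 15.0),
                        (0.55, -120.0, 135.0, 25.0),
                        (0.15, -90.0, 0.0, 30.0))))
    include_structure: bool = True
    #: ground-truth coefficients on encoded columns (incl. "intercept")
    effect_vector: Mapping[str, float] | None = None
    enforce_neg_sequon: bool = True
    forbid_wstw: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be >= 0")
        if self.residue_probs is not None:
            for name, tab in self.residue_probs.items():
                sums = tab.sum(axis=0)
                if not np.allclose(sums, 100.0, atol=1.5):
                    raise ValueError(
                        f"{name}: position probabilities must sum to 100%")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("structure_pos", "structure_neg"):
            if key in raw:
                raw[key] = StructureModel(**raw[key])
        return cls(**raw)


def default_marginals() -> dict[str, pd.DataFrame]:
    """Positive class: published O-GlcNAc marginals.  Negative class: the
    pooled positional background (row means of the positive table) — the
    control-class marginals are not published, so a generic background is
    used, with the sequon constraint imposed on top."""
    pos = reference.load_marginals("oglcnac")
    background = pos.mean(axis=1)
    background = 100.0 * background / background.sum()
    neg = pd.DataFrame({c: background for c in pos.columns})
    return {"positive": pos, "negative": neg}


def sample_from_marginals(marginals: pd.DataFrame, n: int, seed: int,
                          s_fraction: float = 0.5912,
                          half_width: int = 8) -> list[str]:
    """Sample windows position-independently from a residue x offset table.

    The center is fixed to S or T according to ``s_fraction``.  Offsets
    ±1..±half_width must all be present as columns.
    """
    rng = np.random.default_rng(seed)
    offsets = [o for o in range(-half_width, half_width + 1) if o != 0]
    missing = [o for o in offsets if o not in marginals.columns]
    if missing:
        raise KeyError(f"marginal table lacks offset column(s) {missing}")
    residues = list(marginals.index)
    draws = {}
    for o in offsets:
        p = marginals[o].to_numpy(dtype=float)
        p = p / p.sum()
        draws[o] = rng.choice(len(residues), size=n, p=p)
    centers = np.where(rng.random(n) < s_fraction, "S", "T")
    windows = []
    for i in range(n):
        w = [residues[draws[o][i]] if o != 0 else centers[i]
             for o in range(-half_width, half_width + 1)]
        windows.append("".join(w))
    return windows


def _sample_structure(model: StructureModel, n: int,
                      rng: np.random.Generator):
    zero = rng.random(n) < model.p_asa_zero
    asa = np.where(zero, 0.0,
                   rng.lognormal(model.asa_meanlog, model.asa_sdlog, n))
    weights = np.array([m[0] for m in model.rama_modes])
    modes = rng.choice(len(weights), size=n, p=weights / weights.sum())
    phi = np.empty(n)
    psi = np.empty(n)
    for j, (_, mphi, mpsi, sd) in enumerate(model.rama_modes):
        idx = modes == j
        phi[idx] = rng.normal(mphi, sd, idx.sum())
        psi[idx] = rng.normal(mpsi, sd, idx.sum())
    phi = np.clip(phi, -180.0, 180.0)
    psi = np.clip(psi, -180.0, 180.0)
    ss_cats = list(model.ss_probs)
    ss_p = np.array([model.ss_probs[c] for c in ss_cats], dtype=float)
    ss = rng.choice(ss_cats, size=n, p=ss_p / ss_p.sum())
    turns = []
    for i in range(n):
        labels = {t for t, pr in model.turn_probs.items()
                  if rng.random() < pr}
        turns.append(frozenset(labels))
    return asa, phi, psi, ss, turns


def _apply_window_constraints(window: str, positive: bool,
                              cfg: GeneratorConfig,
                              rng: np.random.Generator,
                              marginals: pd.DataFrame) -> str:
    hw = cfg.half_width
    w = list(window)
    if positive and cfg.forbid_wstw:
        while w[hw - 1] == "W" and w[hw + 1] == "W":
            w[hw + 1] = rng.choice([a for a in AMINO_ACIDS if a != "W"])
    if not positive and cfg.enforce_neg_sequon:
        w[hw - 2] = "N"                       # N at -2 of the re-centered site
        while w[hw - 1] == "P":               # never P between N and S/T
            p = marginals[-1].to_numpy(dtype=float)
            p = p / p.sum()
            w[hw - 1] = marginals.index[rng.choice(len(p), p=p)]
    return "".join(w)


def sample_table(config: GeneratorConfig) -> StudyTable:
    """Generate a labeled two-class StudyTable; deterministic given seed.

    Without an effect vector, the class label is the response (positives
    carry the O-glycosylation flags, negatives the N-glycosylation flag
    plus a multi-sugar count).  With ``effect_vector`` set, the response
    is Bernoulli(clamp(x·beta, 0, 1)) on the encoded design — a literal
    LPM data-generating process for recovery tests — and flags follow the
    drawn response.
    """
    rng = np.random.default_rng(config.seed)
    marg = dict(config.residue_probs) if config.residue_probs is not None \
        else default_marginals()
    pos_w = sample_from_marginals(marg["positive"], config.n_pos,
                                  int(rng.integers(2 ** 31)),
                                  config.s_fraction, config.half_width)
    neg_w = sample_from_marginals(marg["negative"], config.n_neg,
                                  int(rng.integers(2 ** 31)),
                                  0.5, config.half_width)
    pos_w = [_apply_window_constraints(w, True, config, rng,
                                       marg["positive"]) for w in pos_w]
    neg_w = [_apply_window_constraints(w, False, config, rng,
                                       marg["negative"]) for w in neg_w]

    records = []
    structs = {}
    if config.include_structure:
        structs["pos"] = _sample_structure(config.structure_pos,
                                           config.n_pos, rng)
        structs["neg"] = _sample_structure(config.structure_neg,
                                           config.n_neg, rng)

    def build(i, window, positive):
        cls = "pos" if positive else "neg"
        idx = i
        length = int(rng.integers(80, 1500))
        site = int(rng.integers(config.half_width + 1,
                                length - config.half_width))
        structure = None
        if config.include_structure:
            asa, phi, psi, ss, turns = structs[cls]
            structure = StructureAnnotation(
                pdb_id=f"{'P' if positive else 'N'}{idx:04d}",
                asa=float(asa[idx]), phi=float(phi[idx]),
                psi=float(psi[idx]), secondary_structure=str(ss[idx]),
                turn_types=turns[idx])
        return SiteRecord(
            accession=f"SYN{cls.upper()}{idx:05d}",
            site_position=site,
            site_residue=window[config.half_width],
            window=window,
            protein_length=length,
            organism="Homo sapiens (Human)",
            flags={},
            structure=structure,
            sugar_count=None if positive else int(2 + rng.poisson(1.0)),
        )

    records = [build(i, w, True) for i, w in enumerate(pos_w)]
    records += [build(i, w, False) for i, w in enumerate(neg_w)]
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)

    if config.effect_vector is not None:
        table = StudyTable(records, provenance="synthetic(effect)")
        dm = encode(table, half_width=config.half_width,
                    include_structure=False, label=labels)
        beta = dict(config.effect_vector)
        p = np.full(dm.n, float(beta.pop("intercept", 0.0)))
        for col, b in beta.items():
            if col not in dm.X.columns:
                raise KeyError(f"effect column {col!r} not in encoded design")
            p += b * dm.X[col].to_numpy()
        labels = (rng.random(dm.n) < np.clip(p, 0.0, 1.0)).astype(int)

    flagged = []
    for rec, lab in zip(records, labels):
        if lab == 1:
            flags = {"Oglycos_status": rec.structure is not None,
                     "Ogly_only_seq": True, "Ogly_21": True}
        else:
            flags = {"glyco_status": True}
        flagged.append(SiteRecord(
            accession=rec.accession, site_position=rec.site_position,
            site_residue=rec.site_residue, window=rec.window,
            protein_length=rec.protein_length, organism=rec.organism,
            flags=flags, structure=rec.structure,
            sugar_count=rec.sugar_count if lab == 0 else None))
    return StudyTable(flagged, provenance=f"synthetic(seed={config.seed})")


def sample_study(seed: int = 0, n_pos: int = 987, n_neg: int = 1083,
                 n_pos_seq: int = 340, n_neg_seq: int = 361,
                 n_oos_pos: int = 259, n_ogal: int = 2079,
                 n_wstw: int = 236,
                 scale: float = 1.0) -> dict[str, StudyTable]:
    """Full synthetic study: every analysis subset, at the study sizes.

    ``scale`` shrinks all sample sizes proportionally (minimum 30) for
    quick runs.  Subsets mirror the estimation design: structural
    in-sample classes, sequence-only in-sample classes, an out-of-sample
    O-GlcNAc set, an O-GalNAc transfer set and a W-S/T-W control set.
    """
    def sz(n):
        return max(30, int(round(n * scale)))

    rng = np.random.default_rng(seed)

    def sub(i):
        return int(rng.integers(2 ** 31))

    marg = default_marginals()
    ogal = reference.load_marginals("ogalnac")

    structural = sample_table(GeneratorConfig(
        n_pos=sz(n_pos), n_neg=sz(n_neg), seed=sub(0)))
    sequence = sample_table(GeneratorConfig(
        n_pos=sz(n_pos_seq), n_neg=sz(n_neg_seq),
        include_structure=False, seed=sub(1)))
    oos = sample_table(GeneratorConfig(
        n_pos=sz(n_oos_pos), n_neg=0, include_structure=False, seed=sub(2)))
    ogal_tab = sample_table(GeneratorConfig(
        n_pos=sz(n_ogal), n_neg=0, include_structure=False,
        residue_probs={"positive": ogal, "negative": marg["negative"]},
        s_fraction=1 - 0.6027, seed=sub(3)))
    from dataclasses import replace as _replace
    ogal_tab = StudyTable(
        [_replace(r, flags={"GALNAC_s1": True}) for r in ogal_tab],
        provenance=ogal_tab.provenance)

    wstw_cfg = GeneratorConfig(n_pos=sz(n_wstw), n_neg=0,
                               include_structure=False,
                               forbid_wstw=False, seed=sub(4))
    wstw = sample_table(wstw_cfg)
    fixed = []
    for r in wstw.records:
        hw = wstw_cfg.half_width
        w = list(r.window)
        w[hw - 1] = "W"
        w[hw + 1] = "W"
        fixed.append(SiteRecord(
            accession=r.accession, site_position=r.site_position,
            site_residue=r.site_residue, window="".join(w),
            protein_length=r.protein_length, organism=r.organism,
            flags={"wstw": True}, structure=None, sugar_count=None))
    wstw = StudyTable(fixed, provenance=wstw.provenance)

    return {"structural": structural, "sequence": sequence,
            "oos_oglcnac": oos, "ogal": ogal_tab, "wstw": wstw}
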