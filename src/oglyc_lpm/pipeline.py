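"""End-to-end study orchestration.

Runs the whole analysis on either a loaded site table or the synthetic
study: derives the analysis subsets, fits the structural and the
sequence-only LPMs (refit mode: minimal-k ridge + weighted LS with
significance pruning; fixture mode: apply the published coefficient
tables), scores the out-of-sample subsets, and emits flat CSV reports.
Also houses the auxiliary structure-from-sequence regressions (psi and
log ASA on the positional indicators).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .encoding import DesignMatrix, encode
from .lpm_estimation import (
    LinearFit,
    drop_degenerate,
    make_full_rank,
    fit_ols,
    fit_to_frame,
    predict,
    predict_and_classify,
    significance_prune,
    stepwise_cv_press,
)
from .model_diagnostics import classifier_diagnostics, ridge_anova
from .sequon_analysis import occurrence_table
from .study_io import (
    StudyTable,
    derive_subsets,
    filter_single_sugar,
    load_study_table,
    unique_seq_extract,
)
from .synthetic_data import sample_study

log = logging.getLogger("oglyc_lpm.pipeline")

SEQUONS = ("N-P-S/T", "N-~P-S/T", "~N-X-S/T", "W-S/T-W",
           "~W-S/T-~W", "~W-S/T-W", "W-S/T-~W")


@dataclass
class PipelineConfig:
    source: str = "synthetic"          # "synthetic" or a csv/xlsx path
    scale: float = 1.0                 # synthetic sample-size multiplier
    seed: int = 0
    alpha: float = 0.05
    cutoff: float = 0.5
    fixture_mode: bool = False
    min_indicator_count: int = 10      # drop rarer indicators before fitting
    output_dir: str | None = None
    extras: dict = field(default_factory=dict)


def _study_subsets(config: PipelineConfig) -> dict[str, StudyTable]:
    if config.source == "synthetic":
        return sample_study(seed=config.seed, scale=config.scale)
    table = load_study_table(config.source)
    subs = derive_subsets(table)
    human = lambda r: "human" in r.organism.lower()
    ngly_h = subs["Ngly"].subset(human)
    ngly_str, _ = filter_single_sugar(ngly_h)
    return {
        "structural": StudyTable(
            subs["dbogap-str"].subset(human).records + ngly_str.records,
            provenance=table.provenance),
        "sequence": StudyTable(
            subs["dbogap-seq"].records
            + unique_seq_extract(ngly_h).records,
            provenance=table.provenance),
        "oos_oglcnac": subs["Oglc-non-dbogap"],
        "ogal": subs["Ogal"],
        "wstw": subs["WSTW-Uniprot"],
    }


def _fit_mode(X: DesignMatrix, config: PipelineConfig, fixture: str):
    if config.fixture_mode:
        coeffs = reference.model_coefficients(fixture)
        missing = [c for c in coeffs if c != "intercept"
                   and c not in X.column_names]
        if missing:
            raise KeyError(f"fixture variables absent from design: {missing}")
        return coeffs, None, None
    Xd = make_full_rank(drop_degenerate(X, min_count=config.min_indicator_count))
    fit, k = significance_prune(Xd, alpha=config.alpha)
    return fit.coefficients, fit, k


def _score_oos(coeffs, table: StudyTable, config: PipelineConfig,
               skip_flanks: bool = False) -> dict:
    X = encode(table, include_structure=False,
               label=[1] * len(table))
    use = dict(coeffs)
    if skip_flanks:
        use = {c: b for c, b in use.items()
               if not (c.startswith(("m1", "p1")) and len(c) == 3)}
    prob, labels, report = predict_and_classify(use, X, config.cutoff)
    report["n"] = len(table)
    report["mispredicted"] = report["false_negative"]
    report["misprediction_rate"] = report["false_negative"] / max(len(table), 1)
    return report


def run_study(config: PipelineConfig) -> dict:
    """Execute the full modeling/validation strategy; returns the report
    bundle and (optionally) writes CSV tables under ``output_dir``."""
    subsets = _study_subsets(config)
    report: dict = {"config": config, "subset_sizes":
                    {k: len(v) for k, v in subsets.items()}}
    for name, size in report["subset_sizes"].items():
        log.info("subset %s: %d records", name, size)

    # --- structural model -------------------------------------------------
    X_str = encode(subsets["structural"], include_structure=True)
    coeffs_str, fit_str, k_str = _fit_mode(
        X_str, config, "structural_wls")
    prob, _, mis = predict_and_classify(coeffs_str, X_str, config.cutoff)
    diag = classifier_diagnostics(
        X_str.y, prob,
        residuals=X_str.y - prob)
    diag.update({"min_k": k_str, "mispredictions": mis})
    if k_str is not None and fit_str is not None and fit_str.columns:
        anova = ridge_anova(X_str.select(fit_str.columns), k_str)
        report["ridge_anova"] = anova.as_frame()
        log.info("structural ridge k=%.5f, anova mse=%.4f", k_str, anova.mse)
    report["structural"] = {"coefficients": coeffs_str, "diagnostics": diag}

    # --- sequence-only model ---------------------------------------------
    X_seq = encode(subsets["sequence"], include_structure=False)
    coeffs_seq, fit_seq, k_seq = _fit_mode(X_seq, config, "sequence_wls")
    prob_seq, _, mis_seq = predict_and_classify(coeffs_seq, X_seq,
                                                config.cutoff)
    diag_seq = classifier_diagnostics(X_seq.y, prob_seq,
                                      residuals=X_seq.y - prob_seq)
    diag_seq.update({"min_k": k_seq, "mispredictions": mis_seq})
    report["sequence"] = {"coefficients": coeffs_seq, "diagnostics": diag_seq}

    # --- out-of-sample scoring -------------------------------------------
    report["oos"] = {
        "oglcnac": _score_oos(coeffs_seq, subsets["oos_oglcnac"], config),
        "ogal": _score_oos(coeffs_seq, subsets["ogal"], config),
        "wstw": _score_oos(coeffs_seq, subsets["wstw"], config,
                           skip_flanks=True),
    }

    # --- sequon occurrence table -----------------------------------------
    report["sequon_table"] = occurrence_table(
        SEQUONS, subsets["oos_oglcnac"])

    if config.output_dir:
        _write_bundle(report, fit_str, fit_seq, Path(config.output_dir))
    return report


def _write_bundle(report, fit_str, fit_seq, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(report["subset_sizes"]).to_csv(outdir / "subset_sizes.csv",
                                             header=["n"])
    report["sequon_table"].to_csv(outdir / "sequon_table.csv", index=False)
    for name, fit in (("structural", fit_str), ("sequence", fit_seq)):
        if fit is not None:
            fit_to_frame(fit).to_csv(outdir / f"lpm_{name}.csv", index=False)
    rows = []
    for model in ("structural", "sequence"):
        d = dict(report[model]["diagnostics"])
        mis = d.pop("mispredictions")
        d.update({f"mis_{k}": v for k, v in mis.items()})
        d["model"] = model
        rows.append(d)
    pd.DataFrame(rows).to_csv(outdir / "diagnostics.csv", index=False)
    pd.DataFrame(report["oos"]).T.to_csv(outdir / "out_of_sample.csv")
    with open(outdir / "run_summary.txt", "w") as fh:
        for model in ("structural", "sequence"):
            d = report[model]["diagnostics"]
            fh.write(f"{model}: KS={d['ks']:.4f} Brier={d['brier']:.4f} "
                     f"DW={d.get('dw', float('nan')):.3f} "
                     f"min_k={d['min_k']}\n")
        for name, r in report["oos"].items():
            fh.write(f"oos {name}: {r['mispredicted']}/{r['n']} "
                     f"({100 * r['misprediction_rate']:.2f}%) mispredicted\n")


def regress_structure_on_sequence(records: StudyTable, target: str,
                                  folds: int = 5, seed: int = 0,
                                  alpha: float = 0.10,
                                  candidates=None,
                                  fixed_columns=None,
                                  label=None) -> tuple[LinearFit, dict]:
    """Regress a structural covariate on sequence information.

    target "psi" uses the backbone psi angle; "log_asa" uses log(ASA)
    with fully buried (ASA = 0) records excluded.  Selection is stepwise
    under CV-PRESS followed by manual pruning on White t-values at the
    ``alpha`` level; pass ``fixed_columns`` to skip selection and fit a
    given variable set.  For log_asa the report includes the KS obtained
    by ranking the binary response on the predicted values.
    """
    if target not in ("psi", "log_asa"):
        raise ValueError("target must be 'psi' or 'log_asa'")
    recs = [r for r in records if r.structure is not None]
    if target == "log_asa":
        recs = [r for r in recs if r.structure.asa > 0]
        yv = np.log([r.structure.asa for r in recs])
    else:
        recs = [r for r in recs if r.structure.psi is not None]
        yv = np.array([r.structure.psi for r in recs])
    if not recs:
        raise ValueError(f"no usable records for target {target}")
    sub = StudyTable(recs, provenance=records.provenance)
    X = encode(sub, include_structure=False)
    X = DesignMatrix(X.X, yv, X.row_keys)
    X = drop_degenerate(X, min_count=5)

    if fixed_columns is not None:
        cols = [c for c in fixed_columns if c in X.column_names]
    else:
        trace = stepwise_cv_press(X, folds=folds, seed=seed,
                                  candidates=candidates)
        cols = trace.selected
    fit = fit_ols(X.select(cols)) if cols else fit_ols(X.select(["pos"]))
    # manual pruning by White t-values
    while True:
        pw = {c: 2 * _norm_sf(abs(fit.coefficients[c]) / fit.white_se[c])
              for c in fit.columns if fit.white_se[c] > 0}
        worst = max(pw, key=pw.get) if pw else None
        if worst is None or pw[worst] <= alpha or len(fit.columns) == 1:
            break
        cols = [c for c in fit.columns if c != worst]
        fit = fit_ols(X.select(cols))
    info = {
        "n": fit.n, "n_variables": len(fit.columns),
        "adjusted_r2": fit.adjusted_r2,
        "ase": float(np.mean(fit.residuals ** 2)),
    }
    if target == "log_asa" and label is not None:
        from .model_diagnostics import ks_statistic
        lab = np.array([label(r) for r in recs])
        if lab.min() != lab.max():
            ks, _ = ks_statistic(lab, fit.fitted)
            info["ks_by_prediction"] = ks
    return fit, info


def _norm_sf(z: float) -> float:
    from scipy.stats import norm
    return float(norm.sf(z))
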