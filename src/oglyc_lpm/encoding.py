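"""Design-matrix construction for the linear probability model.

Each record's residue window is expanded into position-specific amino-acid
indicators named ``m{i}{A}`` (residue A at the i-th position left of the
modified S/T) and ``p{i}{A}`` (right of it).  With a ±8 window and the
``m2*`` block dropped, 140 left and 160 right indicators are defined.  The
``m2*`` block is excluded by default because the negative class carries an
invariant N at that position by construction of the N-glycosylation sequon,
so any other residue there would perfectly flag the positive class.

Additional regressors: ``pos`` (site position over protein length), and —
when structure is included — ``ASA``, the burial dummy ``ASA_zero``, one
dummy per observed turn-type/secondary-structure category, ``phi`` and
``psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .study_io import AMINO_ACIDS, GAP, SiteRecord, StudyTable

#: physicochemical residue groups
RESIDUE_GROUPS = {
    "positively charged": frozenset("RKH"),
    "negatively charged": frozenset("DE"),
    "polar uncharged": frozenset("GNYQSTW"),
    "Cysteine": frozenset("C"),
    "hydrophobic": frozenset("LVIAFMP"),
}


class EncodingError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Named-column numeric matrix with a binary response."""

    X: pd.DataFrame
    y: np.ndarray
    row_keys: list[tuple]

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def select(self, columns: Sequence[str]) -> "DesignMatrix":
        missing = [c for c in columns if c not in self.X.columns]
        if missing:
            raise EncodingError(f"columns absent from design: {missing}")
        return DesignMatrix(self.X.loc[:, list(columns)], self.y, self.row_keys)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "Y", self.y)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignMatrix":
        df = pd.read_csv(path)
        y = df.pop("Y").to_numpy(dtype=float)
        return cls(df, y, [(i,) for i in range(len(df))])


def indicator_columns(half_width: int, drop_minus2: bool = True) -> list[str]:
    cols = []
    for i in range(1, half_width + 1):
        if drop_minus2 and i == 2:
            continue
        cols.extend(f"m{i}{a}" for a in AMINO_ACIDS)
    for i in range(1, half_width + 1):
        cols.extend(f"p{i}{a}" for a in AMINO_ACIDS)
    return cols


def default_label(record: SiteRecord) -> int:
    """1 for O-glycosylated records, 0 for the N-glycosylated controls."""
    positive = ("Oglycos_status", "Ogly_only_seq", "Ogly_21",
                "GLCNAC_s1", "GALNAC_s1")
    return 1 if any(record.flag(f) for f in positive) else 0


def encode(records: StudyTable, half_width: int = 8,
           drop_minus2: bool = True, include_structure: bool = False,
           label: Callable[[SiteRecord], int] | Sequence[int] | None = None,
           ) -> DesignMatrix:
    """Encode records into the LPM design matrix.

    All indicator columns are defined (and may be all-zero) regardless of
    which residues occur; gap-padded window cells contribute all-zero
    indicators.  ``label`` may be a callable or an explicit 0/1 vector;
    by default it is inferred from the subset flags.
    """
    recs = list(records)
    if label is None:
        y = np.array([default_label(r) for r in recs], dtype=float)
    elif callable(label):
        y = np.array([label(r) for r in recs], dtype=float)
    else:
        y = np.asarray(label, dtype=float)
        if len(y) != len(recs):
            raise EncodingError("label vector length mismatch")

    ind_cols = indicator_columns(half_width, drop_minus2)
    col_index = {c: j for j, c in enumerate(ind_cols)}
    X = np.zeros((len(recs), len(ind_cols)))
    pos = np.empty(len(recs))
    for r_i, rec in enumerate(recs):
        if rec.half_width < half_width:
            raise EncodingError(
                f"{rec.accession}: window half-width {rec.half_width} < "
                f"{half_width} and not gap-padded")
        for i in range(1, half_width + 1):
            for side, off in (("m", -i), ("p", i)):
                if side == "m" and drop_minus2 and i == 2:
                    continue
                aa = rec.residue_at(off)
                if aa == GAP:
                    continue
                if aa not in AMINO_ACIDS:
                    raise EncodingError(
                        f"{rec.accession}: unknown residue {aa!r} at {off}")
                X[r_i, col_index[f"{side}{i}{aa}"]] = 1.0
        pos[r_i] = rec.site_position / rec.protein_length

    df = pd.DataFrame(X, columns=ind_cols)
    df["pos"] = pos

    if include_structure:
        no_struct = [r.accession for r in recs if r.structure is None]
        if no_struct:
            raise EncodingError(
                f"structure requested but missing on {len(no_struct)} "
                f"record(s), e.g. {no_struct[:3]}")
        categories = sorted(
            {c for r in recs for c in r.structure.turn_types}
            | {r.structure.secondary_structure for r in recs
               if r.structure.secondary_structure}
        )
        asa = np.array([r.structure.asa for r in recs])
        df["ASA"] = asa
        df["ASA_zero"] = (asa == 0.0).astype(float)
        for cat in categories:
            df[cat] = [
                float(cat in r.structure.turn_types
                      or r.structure.secondary_structure == cat)
                for r in recs
            ]
        df["phi"] = [r.structure.phi if r.structure.phi is not None else 0.0
                     for r in recs]
        df["psi"] = [r.structure.psi if r.structure.psi is not None else 0.0
                     for r in recs]

    return DesignMatrix(df, y, [r.key for r in recs])


def decode_window(row: pd.Series, half_width: int = 8,
                  drop_minus2: bool = True) -> str:
    """Inverse of the indicator encoding (argmax per position); the center
    is rendered as '?' since S/T identity is not encoded."""
    out = []
    for off in range(-half_width, half_width + 1):
        if off == 0:
            out.append("?")
            continue
        if drop_minus2 and off == -2:
            out.append(GAP)
            continue
        prefix = f"m{-off}" if off < 0 else f"p{off}"
        hits = [a for a in AMINO_ACIDS if row.get(f"{prefix}{a}", 0) == 1]
        out.append(hits[0] if hits else GAP)
    return "".join(out)


def recenter_nglyc(record: SiteRecord, offset: int = 2,
                   half_width: int = 8) -> SiteRecord:
    """Re-center an N-glycosylation record on the S/T of its N-X-S/T sequon.

    The N-centered ±10 window becomes an S/T-centered ±``half_width``
    window and the site position moves ``offset`` residues right, so the
    record can be pooled with O-glycosylation records for LPM estimation.
    """
    if offset == 0:
        return record
    if record.site_residue != "N":
        raise EncodingError(f"{record.accession}: center is "
                            f"{record.site_residue!r}, expected N")
    if record.residue_at(1) == "P":
        raise EncodingError(
            f"{record.accession}: P between N and S/T violates the "
            f"N-~P-S/T sequon")
    if record.residue_at(offset) not in "ST":
        raise EncodingError(
            f"{record.accession}: residue at +{offset} is "
            f"{record.residue_at(offset)!r}, not S/T (sequon violation)")
    if record.half_width < offset + half_width:
        raise EncodingError(
            f"{record.accession}: window too narrow to re-center "
            f"(needs ±{offset + half_width})")
    center = record.half_width + offset
    window = record.window[center - half_width: center + half_width + 1]
    return replace(record,
                   site_position=record.site_position + offset,
                   site_residue=record.residue_at(offset),
                   window=window)


def classify_residue_group(residue: str) -> str:
    """Map a residue letter to its physicochemical group label."""
    for label, members in RESIDUE_GROUPS.items():
        if residue in members:
            return label
    raise ValueError(f"not a standard residue: {residue!r}")
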