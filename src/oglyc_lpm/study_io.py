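"""Site-table IO and the named analysis subsets.

The estimation data is a flat table of PTM site records: one row per
(protein, site, structure) triple, with a residue window centered on the
modified residue, boolean subset flags, and optional structural annotation
(ASA, backbone dihedrals, secondary structure, turn types).  This module
loads that table from xlsx/CSV, validates it into :class:`SiteRecord`
objects, and derives the named analysis subsets (``dbogap``, ``dbogap-seq``,
``Oglc-non-dbogap``, ...) by flag selection, uniqueness extraction and
anti-joins keyed on (accession, site position).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: boolean flag columns of the source schema
FLAG_COLUMNS = (
    "Oglycos_status",
    "Ogly_only_seq",
    "Ogly_21",
    "GLCNAC_s1",
    "GALNAC_s1",
    "glyco_status",
    "wstw",
)

_TRUE_TOKENS = {"yes", "y", "1", "true"}

#: canonical column names; source columns are matched case-insensitively
#: after stripping whitespace.  ``sugar_count`` is remappable via the
#: ``column_map`` argument of :func:`load_study_table` because the source
#: file's name for it is not fixed.
REQUIRED_COLUMNS = ("accession", "site_position", "window", "protein_length")
OPTIONAL_COLUMNS = (
    "organism", "pdb_id", "asa", "phi", "psi",
    "secondary_structure", "turn_type", "ligand", "sugar_count",
)

SUBSET_NAMES = (
    "dbogap-str", "dbogap", "dbogap-unique-seq-with-str", "dbogap-seq",
    "Oglc-PS+", "Oglc-non-dbogap", "Ogal", "Ngly", "WSTW-Uniprot",
)


class SchemaError(ValueError):
    """A required column is missing from the source table."""


class ValidationError(ValueError):
    """Rows violate the record invariants (duplicate keys, bad windows...)."""


@dataclass(frozen=True)
class StructureAnnotation:
    pdb_id: str
    asa: float
    phi: float | None = None
    psi: float | None = None
    secondary_structure: str | None = None
    turn_types: frozenset[str] = frozenset()
    ligand: str | None = None

    def __post_init__(self):
        if self.asa < 0:
            raise ValidationError(f"negative ASA {self.asa} for {self.pdb_id}")
        for angle in (self.phi, self.psi):
            if angle is not None and not -180.0 <= angle <= 180.0:
                raise ValidationError(f"dihedral {angle} outside [-180, 180]")


@dataclass(frozen=True)
class SiteRecord:
    accession: str
    site_position: int
    site_residue: str
    window: str
    protein_length: int
    organism: str = ""
    flags: Mapping[str, bool] = field(default_factory=dict)
    structure: StructureAnnotation | None = None
    sugar_count: int | None = None

    def __post_init__(self):
        if not 1 <= self.site_position <= self.protein_length:
            raise ValidationError(
                f"{self.accession}: site {self.site_position} outside protein "
                f"of length {self.protein_length}")
        if len(self.window) % 2 != 1:
            raise ValidationError(f"{self.accession}: even window length")
        center = self.window[len(self.window) // 2]
        if center != self.site_residue:
            raise ValidationError(
                f"{self.accession}: window center {center!r} != site residue "
                f"{self.site_residue!r}")
        bad = set(self.window) - set(AMINO_ACIDS) - {GAP}
        if bad:
            raise ValidationError(f"{self.accession}: unknown residues {bad}")

    @property
    def key(self) -> tuple[str, int, str | None]:
        pdb = self.structure.pdb_id if self.structure else None
        return (self.accession, self.site_position, pdb)

    @property
    def seq_key(self) -> tuple[str, int]:
        return (self.accession, self.site_position)

    @property
    def half_width(self) -> int:
        return len(self.window) // 2

    def residue_at(self, offset: int) -> str:
        """Residue at a signed offset from the site (0 = the site itself)."""
        idx = self.half_width + offset
        if not 0 <= idx < len(self.window):
            raise IndexError(f"offset {offset} outside ±{self.half_width} window")
        return self.window[idx]

    def flag(self, name: str) -> bool:
        return bool(self.flags.get(name, False))


@dataclass
class StudyTable:
    """Ordered collection of records.  Row order is the canonical
    observation order (the Durbin-Watson statistic depends on it)."""

    records: list[SiteRecord]
    provenance: str = ""
    errors: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[tuple, int] = {}
        dupes = []
        for i, r in enumerate(self.records):
            if r.key in seen:
                dupes.append(r.key)
            seen[r.key] = i
        if dupes:
            raise ValidationError(f"duplicate record keys: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def seq_keys(self) -> set[tuple[str, int]]:
        return {r.seq_key for r in self.records}

    def subset(self, predicate) -> "StudyTable":
        return StudyTable([r for r in self.records if predicate(r)],
                          provenance=self.provenance)

    def where_flag(self, name: str) -> "StudyTable":
        return self.subset(lambda r: r.flag(name))


def _coerce_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in _TRUE_TOKENS


def _norm(name: str) -> str:
    return name.strip().lower()


def _build_record(row: Mapping, flags: dict[str, bool]) -> SiteRecord:
    window = str(row["window"]).strip().upper()
    structure = None
    pdb = row.get("pdb_id")
    if pdb is not None and not pd.isna(pdb) and str(pdb).strip():
        asa = row.get("asa")
        turn_raw = row.get("turn_type")
        turns = frozenset(
            t.strip() for t in str(turn_raw).split(",") if t.strip()
        ) if turn_raw is not None and not pd.isna(turn_raw) else frozenset()
        sec = row.get("secondary_structure")
        lig = row.get("ligand")

        def _angle(v):
            return None if v is None or pd.isna(v) else float(v)

        structure = StructureAnnotation(
            pdb_id=str(pdb).strip(),
            asa=float(asa) if asa is not None and not pd.isna(asa) else 0.0,
            phi=_angle(row.get("phi")),
            psi=_angle(row.get("psi")),
            secondary_structure=None if sec is None or pd.isna(sec) else str(sec).strip(),
            turn_types=turns,
            ligand=None if lig is None or pd.isna(lig) else str(lig).strip(),
        )
    sugar = row.get("sugar_count")
    sugar = None if sugar is None or pd.isna(sugar) else int(sugar)
    org = row.get("organism")
    return SiteRecord(
        accession=str(row["accession"]).strip(),
        site_position=int(row["site_position"]),
        site_residue=window[len(window) // 2] if window else "",
        window=window,
        protein_length=int(row["protein_length"]),
        organism="" if org is None or pd.isna(org) else str(org).strip(),
        flags=flags,
        structure=structure,
        sugar_count=sugar,
    )


def load_study_table(path: str | Path, format: str | None = None,
                     column_map: Mapping[str, str] | None = None) -> StudyTable:
    """Load a site table from xlsx (first worksheet) or CSV.

    Unparseable rows are collected into ``StudyTable.errors`` rather than
    silently dropped; a missing required column raises :class:`SchemaError`
    naming it, and duplicate (accession, position, pdb) keys raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "xlsx":
        df = pd.read_excel(path, sheet_name=0)
    elif format == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    rename = {}
    canonical = dict.fromkeys(
        REQUIRED_COLUMNS + OPTIONAL_COLUMNS + FLAG_COLUMNS)
    if column_map:
        for canon, source in column_map.items():
            rename[_norm(source)] = canon
    for canon in canonical:
        rename.setdefault(_norm(canon), canon)
    df = df.rename(columns={c: rename.get(_norm(c), c) for c in df.columns})

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records, errors = [], []
    for i, row in enumerate(df.to_dict(orient="records")):
        flags = {name: _coerce_flag(row.get(name)) for name in FLAG_COLUMNS}
        try:
            records.append(_build_record(row, flags))
        except (ValidationError, ValueError, KeyError, IndexError) as exc:
            errors.append(f"row {i}: {exc}")
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    return StudyTable(records, provenance=f"{path}@{stamp}", errors=errors)


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write the canonical CSV form (round-trips through load_study_table)."""
    rows = []
    for r in table:
        row = {
            "accession": r.accession,
            "site_position": r.site_position,
            "window": r.window,
            "protein_length": r.protein_length,
            "organism": r.organism,
            "sugar_count": r.sugar_count if r.sugar_count is not None else "",
        }
        s = r.structure
        row.update({
            "pdb_id": s.pdb_id if s else "",
            "asa": s.asa if s else "",
            "phi": s.phi if s and s.phi is not None else "",
            "psi": s.psi if s and s.psi is not None else "",
            "secondary_structure": s.secondary_structure if s and s.secondary_structure else "",
            "turn_type": ", ".join(sorted(s.turn_types)) if s else "",
            "ligand": s.ligand if s and s.ligand else "",
        })
        for name in FLAG_COLUMNS:
            row[name] = "yes" if r.flag(name) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def anti_join(a: StudyTable, b_keys: Iterable[tuple[str, int]]) -> StudyTable:
    """Records of ``a`` whose (accession, site_position) is not in ``b_keys``."""
    keys = set(b_keys)
    return a.subset(lambda r: r.seq_key not in keys)


def unique_seq_extract(table: StudyTable) -> StudyTable:
    """First record per unique (accession, site_position), structure dropped."""
    seen: set[tuple[str, int]] = set()
    out = []
    for r in table:
        if r.seq_key not in seen:
            seen.add(r.seq_key)
            out.append(replace(r, structure=None))
    return StudyTable(out, provenance=table.provenance)


def derive_subsets(table: StudyTable) -> dict[str, StudyTable]:
    """Derive the named analysis subsets from the flagged master table.

    ``dbogap-seq`` is the anti-join of ``dbogap`` against the unique
    sequence extract of the structural set; ``Oglc-non-dbogap`` is the
    anti-join of ``Oglc-PS+`` against the union of ``dbogap-seq`` and that
    extract.  Joins key on (accession, site_position).
    """
    dbogap_str = table.where_flag("Oglycos_status")
    dbogap = table.where_flag("Ogly_only_seq")
    uniq = unique_seq_extract(
        dbogap_str.subset(lambda r: "human" in r.organism.lower()
                          or not r.organism))
    dbogap_seq = anti_join(dbogap, uniq.seq_keys())
    oglc_ps = table.where_flag("Ogly_21")
    oglc_non = anti_join(oglc_ps, dbogap_seq.seq_keys() | uniq.seq_keys())
    return {
        "dbogap-str": dbogap_str,
        "dbogap": dbogap,
        "dbogap-unique-seq-with-str": uniq,
        "dbogap-seq": dbogap_seq,
        "Oglc-PS+": oglc_ps,
        "Oglc-non-dbogap": oglc_non,
        "Ogal": table.where_flag("GALNAC_s1"),
        "Ngly": table.where_flag("glyco_status"),
        "WSTW-Uniprot": table.where_flag("wstw"),
    }


def get_subset(subsets: Mapping[str, StudyTable], name: str) -> StudyTable:
    if name not in subsets:
        raise KeyError(
            f"unknown subset {name!r}; valid names: {sorted(subsets)}")
    return subsets[name]


def filter_single_sugar(ngly: StudyTable) -> tuple[StudyTable, dict[str, int]]:
    """Drop N-glycosylation records with a single bound sugar.

    Single-sugar sites are plausible crystallization artifacts and are
    removed from the estimation data.  Returns the retained table and a
    count report.  Records missing ``sugar_count`` are an error — no silent
    pass-through.
    """
    missing = [r.key for r in ngly if r.sugar_count is None]
    if missing:
        raise ValidationError(
            f"sugar_count missing on {len(missing)} record(s), "
            f"e.g. {missing[:3]}")
    kept = ngly.subset(lambda r: r.sugar_count > 1)
    report = {"input": len(ngly), "retained": len(kept),
              "dropped_single_sugar": len(ngly) - len(kept)}
    return kept, report
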