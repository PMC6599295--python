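"""Sequon patterns, occurrence statistics and cross-PTM overlaps.

A sequon is a short '-'-delimited motif evaluated around the modified
residue, e.g. ``N-~P-S/T`` (N, then anything but proline, then the S/T
site) or the composite O-glycosylation consensus ``~(W-S/T-W)``, where
``~`` is logical NOT — applied to a token it negates the residue set,
applied to a parenthesised pattern it negates the whole match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint

from .study_io import AMINO_ACIDS, GAP, SiteRecord, StudyTable

CENTER_RESIDUES = frozenset("STYH")


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class SequonToken:
    residues: frozenset[str]
    negated: bool = False
    is_wildcard: bool = False

    def matches(self, residue: str) -> bool:
        # A terminal gap cannot *be* any residue: it fails positive tokens
        # (including the wildcard) and satisfies negated ones.
        if residue == GAP:
            return self.negated
        if self.is_wildcard:
            return True
        return (residue not in self.residues) if self.negated \
            else (residue in self.residues)

    def text(self) -> str:
        if self.is_wildcard:
            return "~X" if self.negated else "X"
        body = "/".join(sorted(self.residues))
        return f"~{body}" if self.negated else body


@dataclass(frozen=True)
class SequonPattern:
    tokens: tuple[SequonToken, ...]
    center_index: int
    negate_all: bool = False
    source: str = field(default="", compare=False)

    def __invert__(self) -> "SequonPattern":
        return SequonPattern(self.tokens, self.center_index,
                             not self.negate_all)

    @property
    def width_left(self) -> int:
        return self.center_index

    @property
    def width_right(self) -> int:
        return len(self.tokens) - self.center_index - 1


def _parse_token(text: str, position: int) -> SequonToken:
    raw = text.strip()
    negated = raw.startswith("~")
    if negated:
        raw = raw[1:].strip()
    if not raw:
        raise PatternError(f"empty token at position {position}")
    if raw == "X":
        return SequonToken(frozenset(), negated, is_wildcard=True)
    residues = [p.strip() for p in raw.split("/")]
    bad = [r for r in residues if r not in AMINO_ACIDS or len(r) != 1]
    if bad:
        raise PatternError(f"unknown residue(s) {bad} at position {position}")
    return SequonToken(frozenset(residues), negated)


def parse_pattern(text: str) -> SequonPattern:
    """Parse sequon text into a :class:`SequonPattern`.

    Grammar: tokens separated by '-'; each token is an optional '~'
    followed by 'X' or a '/'-separated residue list; the center token is
    the unique S/T-class token, or any token marked with a leading '*'.
    A leading '~( ... )' negates the whole pattern.
    """
    src = text.strip()
    body = src
    negate_all = False
    if body.startswith("~(") and body.endswith(")"):
        negate_all = True
        body = body[2:-1].strip()

    parts = body.split("-")
    tokens, explicit_center = [], []
    for i, part in enumerate(parts):
        p = part.strip()
        if p.startswith("*"):
            explicit_center.append(i)
            p = p[1:]
        tokens.append(_parse_token(p, i + 1))

    if len(explicit_center) > 1:
        raise PatternError("multiple '*' center markers")
    if explicit_center:
        center = explicit_center[0]
    elif len(tokens) == 1:
        center = 0
    else:
        candidates = [
            i for i, t in enumerate(tokens)
            if not t.negated and not t.is_wildcard
            and t.residues <= CENTER_RESIDUES
        ]
        if len(candidates) != 1:
            raise PatternError(
                f"cannot identify a unique center token in {text!r} "
                f"(candidates at {candidates}); mark it with '*'")
        center = candidates[0]
    return SequonPattern(tuple(tokens), center, negate_all, source=src)


def format_pattern(pattern: SequonPattern) -> str:
    """Canonical text form; ``parse_pattern(format_pattern(p)) == p``."""
    body = "-".join(t.text() for t in pattern.tokens)
    return f"~({body})" if pattern.negate_all else body


def match(pattern: SequonPattern, record: SiteRecord) -> bool:
    """Evaluate the pattern with its center token on the modified residue."""
    if (pattern.width_left > record.half_width
            or pattern.width_right > record.half_width):
        raise PatternError(
            f"pattern {format_pattern(pattern)} wider than the "
            f"±{record.half_width} window")
    hit = all(
        tok.matches(record.residue_at(i - pattern.center_index))
        for i, tok in enumerate(pattern.tokens)
    )
    return (not hit) if pattern.negate_all else hit


@dataclass(frozen=True)
class OccurrenceStat:
    count: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    conf_level: float

    def __post_init__(self):
        assert self.ci_low <= self.rate <= self.ci_high


def score_ci(count: int, n: int, conf: float = 0.95,
             method: str = "wilson") -> OccurrenceStat:
    """Binomial rate with a Wilson score confidence interval.

    The score interval reproduces the published intervals for the
    out-of-sample misprediction rate (54/259 -> 16.35%..26.20%) and the
    sequon occurrence rates, which is how the method was pinned down.
    ``method="beta"`` switches to Clopper-Pearson.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    if method not in ("wilson", "beta"):
        raise ValueError("method must be 'wilson' or 'beta'")
    low, high = proportion_confint(count, n, alpha=1 - conf, method=method)
    # exact boundaries (the score interval is degenerate there up to
    # float noise)
    low = 0.0 if count == 0 else float(low)
    high = 1.0 if count == n else float(high)
    return OccurrenceStat(count, n, count / n, low, high, conf)


def occurrence(pattern: SequonPattern | str, table: StudyTable,
               conf: float = 0.95) -> OccurrenceStat:
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    hits = sum(match(pattern, r) for r in table)
    return score_ci(hits, len(table), conf)


def occurrence_table(patterns, table: StudyTable, conf: float = 0.95):
    """Occurrence-rate table for several sequons on one dataset."""
    import pandas as pd

    rows = []
    for pat in patterns:
        parsed = parse_pattern(pat) if isinstance(pat, str) else pat
        stat = occurrence(parsed, table, conf)
        rows.append({
            "sequon": format_pattern(parsed),
            "count": stat.count, "n": stat.n,
            "rate_pct": 100 * stat.rate,
            "ci_low_pct": 100 * stat.ci_low,
            "ci_high_pct": 100 * stat.ci_high,
        })
    return pd.DataFrame(rows)


def ptm_overlap(a: StudyTable, b: StudyTable, offset_a: int = 0) -> StudyTable:
    """Records of ``a`` whose shifted site matches a key in ``b``.

    ``offset_a`` shifts a's positions before comparison — +2 aligns the
    S/T of the N-X-S/T sequon of N-glycosylation records with the modified
    residue of the other PTM.
    """
    b_keys = b.seq_keys()
    return a.subset(
        lambda r: (r.accession, r.site_position + offset_a) in b_keys)
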