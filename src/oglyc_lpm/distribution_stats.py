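"""Descriptive marginal tables and nonparametric comparisons.

Positional amino-acid marginal tables per PTM class, the physicochemical
group summary, Wilcoxon signed-rank comparison of per-residue positional
profiles across two PTM classes, and the rank-sum / two-sample-KS
comparisons of structural covariates (notably ASA) between classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import classify_residue_group
from .study_io import AMINO_ACIDS, GAP, StudyTable


def marginal_table(records: StudyTable, offsets) -> pd.DataFrame:
    """Percentage of each residue at each signed offset.

    Gap cells are excluded from the denominators, so every column of the
    result sums to 100% (up to float error).
    """
    if len(records) == 0:
        raise ValueError("empty table")
    offsets = list(offsets)
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=offsets,
                          dtype=float)
    for r in records:
        for o in offsets:
            aa = r.residue_at(o)
            if aa != GAP:
                counts.loc[aa, o] += 1
    denom = counts.sum(axis=0)
    if (denom == 0).any():
        empty = [o for o in offsets if denom[o] == 0]
        raise ValueError(f"no residues observed at offset(s) {empty}")
    return 100.0 * counts / denom


def group_table(marginals: pd.DataFrame) -> pd.DataFrame:
    """Collapse a residue x offset marginal table into the five
    physicochemical groups (percent per offset)."""
    groups = marginals.index.to_series().map(classify_residue_group)
    return marginals.groupby(groups).sum()


@dataclass
class PairwiseSignificance:
    flags: dict[str, int]            # residue -> 1/0 at alpha
    p_values: dict[str, float]
    alpha: float
    n_pairs: int


def signed_rank_compare(a: pd.DataFrame, b: pd.DataFrame,
                        alpha: float = 0.05) -> PairwiseSignificance:
    """Per-residue Wilcoxon signed-rank test of two positional profiles.

    For each residue, the proportions across the offsets shared by both
    tables are paired and tested (two-sided, Pratt handling of zero
    differences).  A residue is flagged 1 when p < alpha.
    """
    shared = [o for o in a.columns if o in set(b.columns)]
    if not shared:
        raise ValueError("tables share no offsets")
    if len(shared) < 6:
        raise ValueError(f"only {len(shared)} shared offsets; need >= 6")
    flags, pvals = {}, {}
    for residue in a.index:
        x = a.loc[residue, shared].to_numpy(dtype=float)
        y = b.loc[residue, shared].to_numpy(dtype=float)
        if np.all(x == y):
            flags[residue], pvals[residue] = 0, 1.0
            continue
        res = stats.wilcoxon(x, y, zero_method="pratt",
                             alternative="two-sided")
        pvals[residue] = float(res.pvalue)
        flags[residue] = int(res.pvalue < alpha)
    return PairwiseSignificance(flags, pvals, alpha, len(shared))


def rank_sum_compare(x, y):
    """Wilcoxon rank-sum (Mann-Whitney) with normal approximation and tie
    correction.  Returns (statistic, two-sided p, direction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        import warnings
        warnings.warn("all values tied across both samples; p = 1")
        return 0.0, 1.0, "tied"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    direction = "y larger" if res.statistic < len(x) * len(y) / 2 else "x larger"
    return float(res.statistic), float(res.pvalue), direction


def ks_two_sample(x, y):
    """Two-sample KS: sup distance between empirical CDFs, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def asa_by_class(table: StudyTable, label) -> tuple[np.ndarray, np.ndarray]:
    """Split ASA values by a 0/1 labeling callable; (positive, negative)."""
    pos = [r.structure.asa for r in table if r.structure and label(r) == 1]
    neg = [r.structure.asa for r in table if r.structure and label(r) == 0]
    return np.asarray(pos), np.asarray(neg)
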