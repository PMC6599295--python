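"""Linear probability model estimation chain.

The LPM regresses a 0/1 glycosylation outcome on the design matrix by
ordinary least squares, then corrects its built-in heteroscedasticity in
two stages: ridge regression with the smallest tuning parameter k that
forces every fitted probability into [0, 1], and a weighted least-squares
refit with weights 1/(p(1-p)) built from those ridge probabilities.
Variable selection is greedy forward-backward stepwise under K-fold
cross-validated PRESS, and a significance-pruning loop drops predictors
until everything is significant at the chosen level.

Ridge uses the correlation form: predictors centered and scaled to unit
length, penalty k applied on that scale, intercept unpenalized, and
coefficients reported back on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .encoding import DesignMatrix

INTERCEPT = "intercept"


class RankDeficientError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design is rank deficient; dependent/degenerate "
                         f"columns: {self.columns}")


def _check_rank(X: DesignMatrix) -> None:
    mat = np.column_stack([np.ones(X.n), X.values()])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        thresh = diag.max() * max(mat.shape) * np.finfo(float).eps
        names = [INTERCEPT] + X.column_names
        bad = [names[piv[j]] for j in range(len(diag)) if diag[j] < thresh]
        bad += [names[piv[j]] for j in range(len(diag), mat.shape[1])]
        raise RankDeficientError(bad or ["<undetermined>"])


def drop_degenerate(X: DesignMatrix, min_count: int = 1) -> DesignMatrix:
    """Drop constant columns and, for indicators, columns with fewer than
    ``min_count`` ones — convenience before ridge/stepwise on wide designs."""
    keep = []
    for c in X.column_names:
        v = X.X[c].to_numpy()
        if np.ptp(v) == 0:
            continue
        if set(np.unique(v)) <= {0.0, 1.0} and v.sum() < min_count:
            continue
        keep.append(c)
    return X.select(keep)


def make_full_rank(X: DesignMatrix) -> DesignMatrix:
    """Keep a maximal linearly independent column subset (intercept implied).

    Complete indicator blocks (all 20 residues present at a position, or an
    exhaustive category set) are collinear with the intercept; pivoted QR
    picks an estimable subset, returned in original column order.
    """
    from scipy.linalg import qr

    mat = np.column_stack([np.ones(X.n), X.values()])
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return X
    # pivot on the centered predictors so the intercept is always retained
    xc = X.values() - X.values().mean(axis=0)
    _, _, piv = qr(xc, mode="economic", pivoting=True)
    keep_idx = set(piv[:rank - 1])
    keep = [c for j, c in enumerate(X.column_names) if j in keep_idx]
    return X.select(keep)


@dataclass
class LinearFit:
    coefficients: dict[str, float]
    classical_se: dict[str, float]
    white_se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    p: int
    adjusted_r2: float
    press: float | None = None
    weights: np.ndarray | None = None

    @property
    def columns(self) -> list[str]:
        return [c for c in self.coefficients if c != INTERCEPT]


@dataclass
class RidgeFit:
    k: float
    coefficients: dict[str, float]
    fitted: np.ndarray
    centers: dict[str, float]
    scales: dict[str, float]


@dataclass
class StepwiseTrace:
    steps: list[tuple[str, str, float]]  # (action, column, cv_press)
    folds: int
    seed: int
    selected: list[str] = field(default_factory=list)
    intercept_only_press: float | None = None


def _fit_linear(X: DesignMatrix, weights: np.ndarray | None = None) -> LinearFit:
    _check_rank(X)
    exog = sm.add_constant(X.values(), has_constant="add")
    if weights is None:
        res = sm.OLS(X.y, exog).fit()
    else:
        res = sm.WLS(X.y, exog, weights=weights).fit()
    names = [INTERCEPT] + X.column_names
    return LinearFit(
        coefficients=dict(zip(names, res.params)),
        classical_se=dict(zip(names, res.bse)),
        white_se=dict(zip(names, res.HC0_se)),
        t_values=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=X.n, p=len(X.column_names),
        adjusted_r2=float(res.rsquared_adj),
        weights=weights,
    )


def fit_ols(X: DesignMatrix) -> LinearFit:
    """OLS with both classical and White (HC0) standard errors."""
    if X.n <= len(X.column_names) + 1:
        raise ValueError(f"n={X.n} too small for p={len(X.column_names)}")
    return _fit_linear(X)


def white_se(fit: LinearFit, X: DesignMatrix) -> dict[str, float]:
    """HC0 sandwich (X'X)^-1 X' diag(e^2) X (X'X)^-1, diagonal roots."""
    mat = np.column_stack([np.ones(X.n), X.values()])
    xtx_inv = np.linalg.inv(mat.T @ mat)
    meat = mat.T @ (mat * fit.residuals[:, None] ** 2)
    cov = xtx_inv @ meat @ xtx_inv
    names = [INTERCEPT] + X.column_names
    return dict(zip(names, np.sqrt(np.diag(cov))))


def fit_ridge(X: DesignMatrix, k: float) -> RidgeFit:
    """Ridge regression in correlation form at tuning parameter ``k``."""
    if k < 0:
        raise ValueError("ridge k must be >= 0")
    x = X.values()
    y = np.asarray(X.y, dtype=float)
    centers = x.mean(axis=0)
    xc = x - centers
    scales = np.sqrt((xc ** 2).sum(axis=0))
    if np.any(scales == 0):
        bad = [c for c, s in zip(X.column_names, scales) if s == 0]
        raise RankDeficientError(bad)
    z = xc / scales
    yc = y - y.mean()
    a = z.T @ z + k * np.eye(z.shape[1])
    b_std = np.linalg.solve(a, z.T @ yc)
    beta = b_std / scales
    intercept = y.mean() - centers @ beta
    fitted = x @ beta + intercept
    coeffs = {INTERCEPT: float(intercept)}
    coeffs.update(zip(X.column_names, beta))
    return RidgeFit(k=float(k), coefficients=coeffs, fitted=fitted,
                    centers=dict(zip(X.column_names, centers)),
                    scales=dict(zip(X.column_names, scales)))


def _feasible(fitted: np.ndarray, tol: float = 1e-12) -> bool:
    return bool(fitted.min() >= -tol and fitted.max() <= 1 + tol)


def find_min_k(X: DesignMatrix, tol: float = 1e-5,
               k_max: float = 1e6) -> float:
    """Smallest ridge k whose fitted values all lie in [0, 1].

    Returns 0 when OLS predictions are already feasible.  Geometric
    bracketing followed by bisection on the feasibility indicator.
    """
    if _feasible(fit_ridge(X, 0.0).fitted):
        return 0.0
    hi = 1e-4
    while not _feasible(fit_ridge(X, hi).fitted):
        hi *= 2.0
        if hi > k_max:
            raise RuntimeError(f"no feasible k below k_max={k_max}")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _feasible(fit_ridge(X, mid).fitted):
            hi = mid
        else:
            lo = mid
    return hi


def fit_wls_lpm(X: DesignMatrix, ridge: RidgeFit,
                eps: float = 1e-6) -> LinearFit:
    """WLS refit with binomial variance weights from ridge probabilities.

    variance_j = clamp(p_j (1 - p_j), eps, 0.25); weight_j = 1/variance_j.
    """
    p = np.asarray(ridge.fitted)
    var = np.clip(p * (1.0 - p), eps, 0.25)
    return _fit_linear(X, weights=1.0 / var)


def cv_fold_assignment(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Deterministic fold ids; stratified by class for binary responses."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds n={len(y)}")
    assign = np.empty(len(y), dtype=int)
    classes = np.unique(y)
    if folds == len(y):                   # leave-one-out
        return np.arange(len(y))
    if len(classes) <= 2:
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if folds > len(idx):
                raise ValueError(
                    f"folds={folds} exceeds class size {len(idx)}")
            perm = rng.permutation(idx)
            assign[perm] = np.arange(len(perm)) % folds
    else:
        perm = rng.permutation(len(y))
        assign[perm] = np.arange(len(y)) % folds
    return assign


def cv_press(X: DesignMatrix, columns: Sequence[str],
             fold_ids: np.ndarray) -> float:
    """Sum over folds of squared held-out OLS prediction errors."""
    y = np.asarray(X.y, dtype=float)
    mat = np.column_stack([np.ones(X.n), X.select(list(columns)).values()]) \
        if columns else np.ones((X.n, 1))
    total = 0.0
    for f in np.unique(fold_ids):
        test = fold_ids == f
        train = ~test
        beta, *_ = np.linalg.lstsq(mat[train], y[train], rcond=None)
        pred = mat[test] @ beta
        total += float(((y[test] - pred) ** 2).sum())
    return total


def stepwise_cv_press(X: DesignMatrix, folds: int = 10, seed: int = 0,
                      candidates: Sequence[str] | None = None,
                      max_steps: int | None = None,
                      rel_tol: float = 1e-9) -> StepwiseTrace:
    """Greedy forward-backward stepwise selection under CV-PRESS.

    At each step every single add and drop is scored by cross-validated
    PRESS; the best strictly-improving move is taken; the search stops
    when no move improves.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    fold_ids = cv_fold_assignment(np.asarray(X.y), folds, seed)
    pool = [c for c in candidates if c in X.column_names] \
        if candidates is not None else X.column_names
    current: list[str] = []
    best = cv_press(X, current, fold_ids)
    trace = StepwiseTrace(steps=[], folds=folds, seed=seed,
                          intercept_only_press=best)
    while True:
        if max_steps is not None and len(trace.steps) >= max_steps:
            break
        moves = [("add", c) for c in pool if c not in current]
        moves += [("drop", c) for c in current]
        scored = []
        for action, col in moves:
            cols = current + [col] if action == "add" \
                else [c for c in current if c != col]
            try:
                scored.append((cv_press(X, cols, fold_ids), action, col))
            except np.linalg.LinAlgError:
                continue
        if not scored:
            break
        score, action, col = min(scored)
        if score >= best * (1 - rel_tol):
            break
        best = score
        current = current + [col] if action == "add" \
            else [c for c in current if c != col]
        trace.steps.append((action, col, score))
    trace.selected = current
    return trace


def significance_prune(X: DesignMatrix, alpha: float = 0.05,
                       eps: float = 1e-6, reselect: bool = False,
                       folds: int = 10, seed: int = 0,
                       ) -> tuple[LinearFit, float]:
    """Ridge-weighted WLS with iterative drop-worst pruning.

    Loop: minimal-k ridge -> WLS with p(1-p) weights -> if any non-intercept
    p-value exceeds ``alpha``, drop the single worst column and repeat.
    Terminates because the column count strictly decreases.  Returns the
    final fit and the minimal k used for it.

    ``reselect=True`` re-runs the stepwise CV-PRESS search over the
    surviving columns after each drop instead of keeping the remaining
    set fixed (much slower; the candidate pool still only shrinks, so
    termination is preserved).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    current = X
    while True:
        if reselect and current.column_names:
            trace = stepwise_cv_press(current, folds=folds, seed=seed)
            if trace.selected:
                current = current.select(trace.selected)
        if not current.column_names:
            fit = _fit_linear(current)
            return fit, 0.0
        k = find_min_k(current)
        ridge = fit_ridge(current, k)
        fit = fit_wls_lpm(current, ridge, eps=eps)
        pvals = {c: fit.p_values[c] for c in current.column_names}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            return fit, k
        current = current.select(
            [c for c in current.column_names if c != worst])


def predict(coefficients: Mapping[str, float], X: DesignMatrix) -> np.ndarray:
    """Raw linear-index probabilities from a coefficient map."""
    needed = [c for c in coefficients if c != INTERCEPT]
    missing = [c for c in needed if c not in X.column_names]
    if missing:
        raise KeyError(f"design lacks fit column(s): {missing}")
    p = np.full(X.n, float(coefficients.get(INTERCEPT, 0.0)))
    for c in needed:
        p += coefficients[c] * X.X[c].to_numpy(dtype=float)
    return p


def predict_and_classify(fit: LinearFit | Mapping[str, float],
                         X: DesignMatrix, cutoff: float = 0.5):
    """Probabilities, labels and a by-class misprediction report.

    Probabilities are the raw linear index (may leave [0, 1]); a record is
    labeled positive when its probability is >= the cutoff, so a true
    positive is mispredicted exactly when its probability is < cutoff.
    """
    coeffs = fit.coefficients if isinstance(fit, LinearFit) else fit
    prob = predict(coeffs, X)
    labels = (prob >= cutoff).astype(int)
    y = np.asarray(X.y).astype(int)
    report = {
        "n_positive": int((y == 1).sum()),
        "n_negative": int((y == 0).sum()),
        "false_negative": int(((y == 1) & (labels == 0)).sum()),
        "false_positive": int(((y == 0) & (labels == 1)).sum()),
    }
    if report["n_positive"]:
        report["false_negative_rate"] = report["false_negative"] / report["n_positive"]
    if report["n_negative"]:
        report["false_positive_rate"] = report["false_positive"] / report["n_negative"]
    return prob, labels, report


def fit_to_frame(fit: LinearFit, use_white: bool = False) -> pd.DataFrame:
    """Serialize as (variable, beta, abs_t) — the published table layout."""
    se = fit.white_se if use_white else fit.classical_se
    rows = [
        {"variable": c, "beta": b,
         "abs_t": abs(b) / se[c] if se[c] > 0 else np.inf}
        for c, b in fit.coefficients.items()
    ]
    return pd.DataFrame(rows)


def coefficients_from_frame(df: pd.DataFrame) -> dict[str, float]:
    return dict(zip(df["variable"], df["beta"]))
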