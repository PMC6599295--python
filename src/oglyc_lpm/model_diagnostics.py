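"""Classifier and regression diagnostics for the fitted LPM.

Covers the two-sample KS separation of predicted probabilities, the Brier
score, Durbin-Watson serial correlation, Cook's distances, variance
inflation factors, the fractional-degrees-of-freedom ridge ANOVA, and the
repeated cross-validation variability study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .encoding import DesignMatrix
from .lpm_estimation import (
    INTERCEPT,
    LinearFit,
    _fit_linear,
    cv_fold_assignment,
    predict,
)


def ks_statistic(y, p) -> tuple[float, float]:
    """Max vertical distance between class-conditional CDFs of scores.

    Returns (ks, location); the location is the smallest score attaining
    the maximum.  Requires both classes present.
    """
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    p1, p0 = p[y == 1], p[y == 0]
    if len(p1) == 0 or len(p0) == 0:
        raise ValueError("both classes must be present")
    grid = np.unique(p)
    cdf1 = np.searchsorted(np.sort(p1), grid, side="right") / len(p1)
    cdf0 = np.searchsorted(np.sort(p0), grid, side="right") / len(p0)
    gaps = np.abs(cdf1 - cdf0)
    i = int(np.argmax(gaps))  # argmax returns the first (smallest) maximizer
    return float(gaps[i]), float(grid[i])


def brier(y, p) -> float:
    """Mean squared difference between outcomes and predicted probabilities."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y - p) ** 2))


def durbin_watson(residuals) -> float:
    """First-order serial correlation ratio in source-file row order."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_dw(e))


def cooks_distance(fit: LinearFit, X: DesignMatrix,
                   flag_threshold: float = 0.5):
    """Cook's D per observation, D_i = e_i^2 h_i / (p s^2 (1-h_i)^2).

    Uses the fit's weights when present (weighted hat matrix).  Returns
    (distances, indices with D above the threshold).
    """
    mat = np.column_stack([np.ones(X.n), X.values()])
    w = fit.weights if fit.weights is not None else np.ones(X.n)
    sw = np.sqrt(w)
    mw = mat * sw[:, None]
    xtx_inv = np.linalg.inv(mw.T @ mw)
    h = np.einsum("ij,jk,ik->i", mw, xtx_inv, mw)
    p = mat.shape[1]
    e = fit.residuals * sw
    s2 = float((e ** 2).sum() / (X.n - p))
    d = e ** 2 * h / (p * s2 * (1 - h) ** 2)
    return d, np.flatnonzero(d > flag_threshold)


def vif(X: DesignMatrix) -> dict[str, float]:
    """Variance inflation factor 1/(1-R²) per column; infinite VIF marks
    perfect collinearity."""
    cols = X.column_names
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    out = {}
    for c in cols:
        others = [o for o in cols if o != c]
        a = np.column_stack([np.ones(X.n)] +
                            [X.X[o].to_numpy(dtype=float) for o in others])
        yv = X.X[c].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(a, yv, rcond=None)
        resid = yv - a @ beta
        sst = float(((yv - yv.mean()) ** 2).sum())
        sse = float((resid ** 2).sum())
        if sst == 0:
            out[c] = np.inf
            continue
        r2 = 1 - sse / sst
        out[c] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class RidgeAnova:
    """Fractional-df ANOVA decomposition of a ridge fit.

    Ridge shrinkage breaks least-squares orthogonality, so the total sum
    of squares splits into regression, residual and a nonorthogonal
    component (the residual-fit cross term), with effective degrees of
    freedom from the ridge hat matrix: df_reg = tr(H)-1,
    df_res = n - tr(2H - H²), df_non = tr(H) - tr(H²); the three always
    sum to n-1 and collapse to the classical table at k = 0.
    """

    df_reg: float
    df_res: float
    df_non: float
    ss_reg: float
    ss_res: float
    ss_non: float
    ss_total: float
    mse: float
    f_approx: float
    angle_deg: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": "Regression", "df": self.df_reg, "ss": self.ss_reg,
             "ms": self.ss_reg / self.df_reg, "f_approx": self.f_approx,
             "angle_deg": self.angle_deg},
            {"source": "Residual", "df": self.df_res, "ss": self.ss_res,
             "ms": self.mse},
            {"source": "Nonorthogonal", "df": self.df_non, "ss": self.ss_non},
            {"source": "Total", "df": self.df_reg + self.df_res + self.df_non,
             "ss": self.ss_total},
        ])


def ridge_anova(X: DesignMatrix, k: float) -> RidgeAnova:
    if k < 0:
        raise ValueError("k must be >= 0")
    x = X.values()
    y = np.asarray(X.y, dtype=float)
    n = len(y)
    centers = x.mean(axis=0)
    xc = x - centers
    scales = np.sqrt((xc ** 2).sum(axis=0))
    if np.any(scales == 0):
        raise ValueError("constant column in design")
    z = xc / scales
    core = np.linalg.solve(z.T @ z + k * np.eye(z.shape[1]), z.T)
    hz = z @ core                      # centered-part hat matrix
    yc = y - y.mean()
    fitted_c = hz @ yc
    e = yc - fitted_c
    # effective df from H = (1/n)J + hz: tr(H) = 1 + tr(hz)
    tr_h = 1.0 + float(np.trace(hz))
    tr_h2 = 1.0 + float(np.sum(hz * hz.T))  # J and hz cross-terms vanish
    df_reg = tr_h - 1.0
    df_res = n - 2.0 * tr_h + tr_h2
    df_non = tr_h - tr_h2
    ss_total = float(yc @ yc)
    ss_reg = float(fitted_c @ fitted_c)
    ss_res = float(e @ e)
    ss_non = 2.0 * float(e @ fitted_c)
    mse = ss_res / df_res
    f_approx = (ss_reg / df_reg) / mse if df_reg > 0 else np.nan
    denom = np.linalg.norm(fitted_c) * np.linalg.norm(e)
    cosang = float(fitted_c @ e) / denom if denom > 0 else 0.0
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return RidgeAnova(df_reg, df_res, df_non, ss_reg, ss_res, ss_non,
                      ss_total, mse, f_approx, angle)


def classifier_diagnostics(y, p, residuals=None, cutoff: float = 0.5) -> dict:
    """Flat diagnostic summary for one model's predictions."""
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    ks, loc = ks_statistic(y, p)
    out = {
        "ks": ks, "ks_location": loc, "brier": brier(y, p),
        "mean_p_pos": float(p[y == 1].mean()),
        "mean_p_neg": float(p[y == 0].mean()),
        "sd_p_pos": float(p[y == 1].std(ddof=1)) if (y == 1).sum() > 1 else 0.0,
        "sd_p_neg": float(p[y == 0].std(ddof=1)) if (y == 0).sum() > 1 else 0.0,
        "false_negative": int(((y == 1) & (p < cutoff)).sum()),
        "false_positive": int(((y == 0) & (p >= cutoff)).sum()),
    }
    if residuals is not None:
        out["dw"] = durbin_watson(residuals)
    return out


def cv_variability(X: DesignMatrix, fixed_columns, folds: int = 5,
                   repeats: int = 20, seed: int = 0) -> pd.DataFrame:
    """Refit coefficients of a fixed variable set per CV split; KS and
    Brier on each held-out fold.  repeats x folds rows."""
    Xs = X.select(list(fixed_columns))
    y = np.asarray(Xs.y)
    rows = []
    for rep in range(repeats):
        fold_ids = cv_fold_assignment(y, folds, seed + rep)
        for f in range(folds):
            test = fold_ids == f
            train_idx = np.flatnonzero(~test)
            sub = DesignMatrix(Xs.X.iloc[train_idx], y[~test],
                               [Xs.row_keys[i] for i in train_idx])
            fit = _fit_linear(sub)
            p_test = predict(fit.coefficients,
                             DesignMatrix(Xs.X.iloc[np.flatnonzero(test)],
                                          y[test], []))
            # single-class folds (e.g. leave-one-out) have no KS
            if y[test].min() != y[test].max():
                ks, _ = ks_statistic(y[test], p_test)
            else:
                ks = np.nan
            rows.append({"repeat": rep, "fold": int(f), "ks": ks,
                         "brier": brier(y[test], p_test)})
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "ks_mean": df["ks"].mean(), "ks_sd": df["ks"].std(ddof=1),
        "brier_mean": df["brier"].mean(), "brier_sd": df["brier"].std(ddof=1),
        "brier_snr": df["brier"].mean() / df["brier"].std(ddof=1)
        if df["brier"].std(ddof=1) > 0 else np.inf,
    }
    return df
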