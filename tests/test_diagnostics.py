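"""KS separation, Brier, Durbin-Watson, Cook's D, VIF, ridge ANOVA and
CV variability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oglyc_lpm.encoding import DesignMatrix
from oglyc_lpm.lpm_estimation import fit_ols, fit_ridge
from oglyc_lpm.model_diagnostics import (
    brier,
    classifier_diagnostics,
    cooks_distance,
    cv_variability,
    durbin_watson,
    ks_statistic,
    ridge_anova,
    vif,
)


def dm(X, y):
    X = pd.DataFrame(X)
    X.columns = [str(c) for c in X.columns]
    return DesignMatrix(X.reset_index(drop=True), np.asarray(y, dtype=float),
                        [(i,) for i in range(len(X))])


class TestKs:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        ks, loc = ks_statistic(y, p)
        assert ks == 1.0 and 0.3 <= loc < 0.7

    def test_identical_scores_zero(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([0.5, 0.5, 0.5, 0.5])
        assert ks_statistic(y, p)[0] == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ks_statistic(np.ones(5), np.random.rand(5))

    def test_matches_threshold_grid_oracle(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 200)
        p = np.clip(0.3 * y + rng.normal(0.4, 0.2, 200), 0, 1)
        ks, _ = ks_statistic(y, p)
        grid = np.linspace(0, 1, 10_001)
        f1 = np.array([(p[y == 1] <= c).mean() for c in grid])
        f0 = np.array([(p[y == 0] <= c).mean() for c in grid])
        assert ks == pytest.approx(np.abs(f1 - f0).max(), abs=1e-12)

    def test_equals_two_sample_ks_distance(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 300)
        p = rng.random(300) + 0.2 * y
        ks, _ = ks_statistic(y, p)
        ref = stats.ks_2samp(p[y == 1], p[y == 0]).statistic
        assert ks == pytest.approx(ref, abs=1e-12)

    def test_location_smallest_maximizer(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        _, loc = ks_statistic(y, p)
        assert loc == 0.2                 # first score attaining the max


class TestBrier:
    def test_perfect_predictions(self):
        y = np.array([0.0, 1.0, 1.0])
        assert brier(y, y) == 0.0

    def test_half_everywhere(self):
        assert brier(np.array([0, 1, 0, 1]), np.full(4, 0.5)) == 0.25

    def test_prevalence_constant_at_most_quarter(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 50).astype(float)
            if y.min() == y.max():
                continue
            assert brier(y, np.full(50, y.mean())) <= 0.25


class TestDurbinWatson:
    def test_alternating_closed_form(self):
        e = np.tile([1.0, -1.0], 50)
        assert durbin_watson(e) == pytest.approx(4 * 99 / 100)

    def test_constant_residuals(self):
        assert durbin_watson(np.full(50, 2.5)) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(10))

    def test_iid_near_two(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=10_000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.05)


class TestCooks:
    def test_leave_one_out_oracle_ten_points(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=10)})
        y = 1.0 + 2.0 * X["x"].to_numpy() + 0.3 * rng.normal(size=10)
        d = dm(X, y)
        fit = fit_ols(d)
        dist, _ = cooks_distance(fit, d)
        mat = np.column_stack([np.ones(10), X.to_numpy()])
        p = 2
        s2 = (fit.residuals ** 2).sum() / (10 - p)
        full_hat = mat @ np.linalg.inv(mat.T @ mat) @ mat.T
        yhat = full_hat @ y
        for i in range(10):
            keep = np.arange(10) != i
            beta_i = np.linalg.lstsq(mat[keep], y[keep], rcond=None)[0]
            yhat_i = mat @ beta_i
            oracle = ((yhat - yhat_i) ** 2).sum() / (p * s2)
            assert dist[i] == pytest.approx(oracle, rel=1e-8)

    def test_duplicated_observation_leverage_dilution(self):
        rng = np.random.default_rng(4)
        base_x = np.append(rng.normal(size=9), 5.0)   # one outlying point
        base_y = 2 * base_x + rng.normal(size=10)
        d1 = dm({"x": base_x}, base_y)
        dist1, _ = cooks_distance(fit_ols(d1), d1)
        x_dup = np.append(base_x, [5.0] * 20)
        y_dup = np.append(base_y, [base_y[-1]] * 20)
        d2 = dm({"x": x_dup}, y_dup)
        dist2, _ = cooks_distance(fit_ols(d2), d2)
        assert dist2[9] < dist1[9]

    def test_balanced_design_below_threshold(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": np.linspace(-1, 1, 40)})
        y = X["x"].to_numpy() + 0.1 * rng.normal(size=40)
        d = dm(X, y)
        dist, flagged = cooks_distance(fit_ols(d), d)
        assert dist.max() < 0.5 and len(flagged) == 0


class TestVif:
    def test_exactly_orthogonal_centered(self):
        # columns orthogonal and centered -> R^2 = 0 exactly
        X = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1],
                          "c": [1.0, -1, -1, 1]})
        v = vif(dm(X, np.zeros(4)))
        assert all(val == pytest.approx(1.0, abs=1e-10) for val in v.values())

    def test_duplicate_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                          "c": [4.0, 3, 2, 1]})
        v = vif(dm(X, np.zeros(4)))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X["d"] = 0.7 * X["a"] + 0.3 * rng.normal(size=50)
        d = dm(X, np.zeros(50))
        v = vif(d)
        import statsmodels.api as sm
        for c in "abcd":
            others = [o for o in "abcd" if o != c]
            r2 = sm.OLS(X[c], sm.add_constant(X[others])).fit().rsquared
            assert v[c] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestRidgeAnova:
    def _design(self, seed=7, n=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = (0.4 + 0.3 * X["a"] - 0.2 * X["b"]
             + 0.3 * rng.normal(size=n) > 0.4).astype(float)
        return dm(X, y)

    def test_k_zero_recovers_classical_anova(self):
        d = self._design()
        an = ridge_anova(d, 0.0)
        assert an.ss_non == pytest.approx(0.0, abs=1e-8)
        assert an.df_non == pytest.approx(0.0, abs=1e-8)
        assert an.df_reg == pytest.approx(4.0, abs=1e-8)
        assert an.df_res == pytest.approx(d.n - 5, abs=1e-8)
        assert an.angle_deg == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("k", [0.0, 0.5, 3.0, 25.0])
    def test_sum_invariants(self, k):
        d = self._design(seed=8)
        an = ridge_anova(d, k)
        assert an.df_reg + an.df_res + an.df_non == pytest.approx(
            d.n - 1, abs=1e-3)
        assert an.ss_reg + an.ss_res + an.ss_non == pytest.approx(
            an.ss_total, rel=1e-3)
        assert an.mse == pytest.approx(an.ss_res / an.df_res)

    def test_positive_k_bends_angle_below_ninety(self):
        d = self._design(seed=9)
        an = ridge_anova(d, 5.0)
        assert an.angle_deg < 90.0
        assert an.ss_non > 0.0

    def test_consistent_with_fit_ridge_fitted_values(self):
        d = self._design(seed=10)
        k = 2.0
        an = ridge_anova(d, k)
        fitted = fit_ridge(d, k).fitted
        yc = d.y - d.y.mean()
        assert an.ss_reg == pytest.approx(
            float(((fitted - d.y.mean()) ** 2).sum()))
        assert an.ss_res == pytest.approx(float(((d.y - fitted) ** 2).sum()))


class TestCvVariability:
    def test_zero_noise_ks_one_every_fold(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(-2, 0.3, 40), rng.normal(2, 0.3, 40)])
        y = (x > 0).astype(float)
        d = dm({"x": x}, y)
        out = cv_variability(d, ["x"], folds=4, repeats=2, seed=0)
        assert (out["ks"] == 1.0).all()

    def test_loo_brier_equals_press_over_n(self):
        rng = np.random.default_rng(12)
        n = 24
        x = rng.normal(size=n)
        y = (x + 0.5 * rng.normal(size=n) > 0).astype(float)
        d = dm({"x": x}, y)
        out = cv_variability(d, ["x"], folds=n, repeats=1, seed=0)
        # brute-force leave-one-out PRESS
        mat = np.column_stack([np.ones(n), x])
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            beta = np.linalg.lstsq(mat[keep], y[keep], rcond=None)[0]
            press += float((y[i] - mat[i] @ beta) ** 2)
        assert out["brier"].sum() == pytest.approx(press)
        assert out["brier"].mean() == pytest.approx(press / n)


class TestClassifierDiagnostics:
    def test_summary_fields(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 100)
        p = np.clip(0.6 * y + 0.2 + 0.1 * rng.normal(size=100), 0, 1)
        out = classifier_diagnostics(y, p, residuals=y - p)
        assert set(out) >= {"ks", "brier", "dw", "mean_p_pos", "mean_p_neg",
                            "false_negative", "false_positive"}
        assert 0 <= out["ks"] <= 1 and out["brier"] >= 0
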