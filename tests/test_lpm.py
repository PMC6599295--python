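"""Estimation chain: OLS, White SEs, ridge, minimal-k, WLS, stepwise,
pruning, prediction."""

import numpy as np
import pandas as pd
import pytest

from oglyc_lpm.encoding import DesignMatrix
from oglyc_lpm.lpm_estimation import (
    INTERCEPT,
    RankDeficientError,
    coefficients_from_frame,
    cv_fold_assignment,
    cv_press,
    find_min_k,
    fit_ols,
    fit_ridge,
    fit_to_frame,
    fit_wls_lpm,
    make_full_rank,
    predict,
    predict_and_classify,
    significance_prune,
    stepwise_cv_press,
    white_se,
)


def dm(X, y):
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    X.columns = [str(c) for c in X.columns]
    return DesignMatrix(X.reset_index(drop=True), np.asarray(y, dtype=float),
                        [(i,) for i in range(len(X))])


class TestOls:
    def test_exact_line(self):
        d = dm({"x": [0.0, 1.0, 2.0]}, [0.0, 1.0, 2.0])
        fit = fit_ols(d)
        assert fit.coefficients["x"] == pytest.approx(1.0)
        assert fit.coefficients[INTERCEPT] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, toy_design):
        fit = fit_ols(toy_design)
        mat = np.column_stack([np.ones(toy_design.n), toy_design.values()])
        beta = np.linalg.solve(mat.T @ mat, mat.T @ toy_design.y)
        got = np.array([fit.coefficients[c] for c in
                        [INTERCEPT] + toy_design.column_names])
        assert np.allclose(got, beta, atol=1e-10)

    def test_t_equals_beta_over_se(self, toy_design):
        fit = fit_ols(toy_design)
        for c in fit.coefficients:
            assert abs(fit.t_values[c]) == pytest.approx(
                abs(fit.coefficients[c]) / fit.classical_se[c])

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(RankDeficientError) as err:
            fit_ols(dm(X, [1, 2, 3, 4]))
        assert set(err.value.columns) & {"a", "b"}

    def test_make_full_rank_restores_estimability(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10],
                          "c": [1.0, 0, 1, 0, 1]})
        fixed = make_full_rank(dm(X, [1, 2, 3, 4, 5]))
        assert len(fixed.column_names) == 2
        fit_ols(fixed)                    # no raise


class TestWhiteSe:
    def test_zero_residuals_zero_se(self):
        d = dm({"x": [0.0, 1.0, 2.0, 3.0]}, [0.0, 1.0, 2.0, 3.0])
        fit = fit_ols(d)
        se = white_se(fit, d)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in se.values())

    def test_six_observation_hand_sandwich(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.3, 5.7])
        d = dm(X, y)
        fit = fit_ols(d)
        mat = np.column_stack([np.ones(6), X.to_numpy()])
        beta = np.linalg.solve(mat.T @ mat, mat.T @ y)
        e = y - mat @ beta
        bread = np.linalg.inv(mat.T @ mat)
        meat = sum(np.outer(mat[i], mat[i]) * e[i] ** 2 for i in range(6))
        hand = np.sqrt(np.diag(bread @ meat @ bread))
        got = white_se(fit, d)
        assert got[INTERCEPT] == pytest.approx(hand[0])
        assert got["x"] == pytest.approx(hand[1])

    def test_matches_statsmodels_hc0(self, toy_design):
        fit = fit_ols(toy_design)
        ours = white_se(fit, toy_design)
        for c in fit.white_se:
            assert ours[c] == pytest.approx(fit.white_se[c], rel=1e-8)

    def test_homoscedastic_agrees_with_classical_asymptotically(self):
        rng = np.random.default_rng(12)
        n = 10_000
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = 1.0 + 0.5 * X["x1"] - 0.25 * X["x2"] + rng.normal(size=n)
        fit = fit_ols(dm(X, y))
        for c in ("x1", "x2"):
            assert fit.white_se[c] == pytest.approx(fit.classical_se[c],
                                                    rel=0.05)


class TestRidge:
    def test_k_zero_reproduces_ols(self, toy_design):
        ols = fit_ols(toy_design)
        ridge = fit_ridge(toy_design, 0.0)
        for c in ols.coefficients:
            assert ridge.coefficients[c] == pytest.approx(
                ols.coefficients[c], abs=1e-8)

    def test_huge_k_shrinks_to_mean(self, toy_design):
        ridge = fit_ridge(toy_design, 1e9)
        for c in toy_design.column_names:
            assert abs(ridge.coefficients[c]) < 1e-6
        assert np.allclose(ridge.fitted, toy_design.y.mean(), atol=1e-4)

    def test_closed_form_two_predictor_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 0.5 + X["a"] - 0.5 * X["b"] + 0.2 * rng.normal(size=30)
        d = dm(X, y)
        k = 2.5
        ridge = fit_ridge(d, k)
        # independent closed form on the unit-length scale
        x = X.to_numpy()
        xc = x - x.mean(axis=0)
        s = np.sqrt((xc ** 2).sum(axis=0))
        z = xc / s
        b_std = np.linalg.inv(z.T @ z + k * np.eye(2)) @ z.T @ (y - y.mean())
        beta = b_std / s
        assert ridge.coefficients["a"] == pytest.approx(beta[0])
        assert ridge.coefficients["b"] == pytest.approx(beta[1])

    def test_negative_k_rejected(self, toy_design):
        with pytest.raises(ValueError):
            fit_ridge(toy_design, -0.1)


class TestMinK:
    def _infeasible_design(self, seed=8, n=30):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        eta = 0.5 + 1.5 * X["a"] - 1.0 * X["b"]
        y = (eta + 0.3 * rng.normal(size=n) > 0.5).astype(float)
        return dm(X, y)

    def test_feasible_returns_zero(self):
        d = dm({"x": [0.1, 0.2, 0.3, 0.4]}, [0.2, 0.25, 0.3, 0.35])
        assert find_min_k(d) == 0.0

    def test_agrees_with_grid_search_oracle(self):
        d = self._infeasible_design()
        k = find_min_k(d, tol=1e-5)
        assert k > 0
        # dense grid around the answer at 1e-6 resolution
        grid = np.arange(max(k - 2e-5, 0.0), k + 2e-5, 1e-6)
        feas = []
        for g in grid:
            f = fit_ridge(d, g).fitted
            feas.append(f.min() >= -1e-12 and f.max() <= 1 + 1e-12)
        first = grid[int(np.argmax(feas))]
        assert abs(k - first) <= 1.1e-5

    def test_feasibility_monotone_over_bracket(self):
        d = self._infeasible_design(seed=9)
        k = find_min_k(d)
        for mult in (1.5, 3.0, 10.0):
            f = fit_ridge(d, k * mult).fitted
            assert f.min() >= -1e-9 and f.max() <= 1 + 1e-9


class TestWls:
    def test_equal_weights_equals_ols_bit_for_bit(self, toy_design):
        from oglyc_lpm.lpm_estimation import RidgeFit
        ols = fit_ols(toy_design)
        ridge = RidgeFit(0.0, {}, np.full(toy_design.n, 0.5), {}, {})
        wls = fit_wls_lpm(toy_design, ridge)
        for c in ols.coefficients:
            assert wls.coefficients[c] == pytest.approx(
                ols.coefficients[c], abs=1e-12)

    def test_boundary_probabilities_clamped(self, toy_design):
        from oglyc_lpm.lpm_estimation import RidgeFit
        p = np.zeros(toy_design.n)
        p[::2] = 1.0
        ridge = RidgeFit(1.0, {}, p, {}, {})
        wls = fit_wls_lpm(toy_design, ridge, eps=1e-6)
        assert np.all(np.isfinite(wls.weights))
        assert wls.weights.max() == pytest.approx(1e6)

    def test_matches_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        y = rng.random(8)
        d = dm(X, y)
        from oglyc_lpm.lpm_estimation import RidgeFit
        phat = np.clip(rng.random(8), 0.1, 0.9)
        ridge = RidgeFit(0.5, {}, phat, {}, {})
        wls = fit_wls_lpm(d, ridge)
        w = 1.0 / (phat * (1 - phat))
        mat = np.column_stack([np.ones(8), X.to_numpy()])
        beta = np.linalg.solve(mat.T @ (mat * w[:, None]),
                               mat.T @ (w * y))
        got = [wls.coefficients[c] for c in [INTERCEPT, "a", "b"]]
        assert np.allclose(got, beta, atol=1e-10)


class TestStepwise:
    def _one_true_column(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 11)),
                         columns=["true"] + [f"noise{i}" for i in range(10)])
        y = 0.4 + 0.35 * X["true"] + 0.15 * rng.normal(size=n)
        return dm(X, y)

    def test_true_column_selected_first(self):
        first = [stepwise_cv_press(self._one_true_column(s), folds=10,
                                   seed=s).steps[0][1]
                 for s in range(20)]
        assert sum(f == "true" for f in first) >= 19

    def test_empty_candidate_pool(self, toy_design):
        trace = stepwise_cv_press(toy_design, folds=5, seed=0, candidates=[])
        assert trace.steps == [] and trace.selected == []
        assert trace.intercept_only_press is not None

    def test_intercept_only_press_by_hand(self):
        y = np.array([0.0, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        d = dm({"x": np.arange(10.0)}, y)
        fold_ids = cv_fold_assignment(y, 2, seed=3)
        got = cv_press(d, [], fold_ids)
        expected = 0.0
        for f in (0, 1):
            tr = y[fold_ids != f]
            te = y[fold_ids == f]
            expected += float(((te - tr.mean()) ** 2).sum())
        assert got == pytest.approx(expected)

    def test_folds_exceeding_class_size_error(self):
        y = np.array([0.0, 1, 0, 1])
        d = dm({"x": [1.0, 2, 3, 4]}, y)
        with pytest.raises(ValueError):
            stepwise_cv_press(d, folds=3, seed=0)


class TestSignificancePrune:
    def test_strong_model_single_pass(self):
        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float),
                          "b": rng.integers(0, 2, n).astype(float)})
        p = 0.2 + 0.3 * X["a"] + 0.25 * X["b"]
        y = (rng.random(n) < p).astype(float)
        fit, k = significance_prune(dm(X, y), alpha=0.05)
        assert set(fit.columns) == {"a", "b"}

    def test_noise_column_pruned(self):
        pruned = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            n = 400
            X = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float),
                              "noise": rng.normal(size=n)})
            p = 0.25 + 0.45 * X["a"]
            y = (rng.random(n) < p).astype(float)
            fit, _ = significance_prune(dm(X, y), alpha=0.05)
            pruned += "noise" not in fit.columns
        assert pruned >= 25

    def test_reselect_variant_prunes_and_reselects(self):
        rng = np.random.default_rng(8)
        n = 300
        X = pd.DataFrame({"a": rng.integers(0, 2, n).astype(float),
                          "b": rng.integers(0, 2, n).astype(float),
                          "noise": rng.normal(size=n)})
        p = 0.2 + 0.3 * X["a"] + 0.25 * X["b"]
        y = (rng.random(n) < p).astype(float)
        fit, _ = significance_prune(dm(X, y), alpha=0.05, reselect=True,
                                    folds=5, seed=0)
        assert "a" in fit.columns and "b" in fit.columns
        assert all(fit.p_values[c] <= 0.05 for c in fit.columns)

    def test_final_fit_all_significant(self):
        rng = np.random.default_rng(6)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"x{i}" for i in range(6)])
        p = np.clip(0.4 + 0.3 * X["x0"], 0.01, 0.99)
        y = (rng.random(n) < p).astype(float)
        fit, _ = significance_prune(dm(X, y), alpha=0.05)
        assert all(fit.p_values[c] <= 0.05 for c in fit.columns)


class TestPredictClassify:
    def test_intercept_only_all_positive(self, toy_design):
        prob, labels, report = predict_and_classify(
            {INTERCEPT: 0.7}, toy_design, cutoff=0.5)
        assert np.all(prob == 0.7) and np.all(labels == 1)

    def test_cutoff_tie_is_positive(self):
        d = dm({"x": [1.0, 1.0]}, [1.0, 0.0])
        _, labels, _ = predict_and_classify({INTERCEPT: 0.5}, d, cutoff=0.5)
        assert list(labels) == [1, 1]

    def test_missing_columns_error(self, toy_design):
        with pytest.raises(KeyError, match="lacks"):
            predict({INTERCEPT: 0.0, "nope": 1.0}, toy_design)

    def test_published_sequence_model_scores_q16566_negative(self):
        """The published sequence-only model assigns the annotated
        O-glycosylation site of Q16566 a slightly negative probability
        (about -7.2%)."""
        from oglyc_lpm import reference
        from oglyc_lpm.encoding import encode
        from oglyc_lpm.study_io import SiteRecord, StudyTable
        w = "VESELGRGATSIVYRCKQKGT"
        rec = SiteRecord("Q16566", 58, "S", w, 473)
        X = encode(StudyTable([rec]), include_structure=False)
        p = predict(reference.model_coefficients("sequence_wls"), X)
        assert p[0] == pytest.approx(-0.072, abs=0.002)


class TestSerialization:
    def test_round_trip(self, toy_design, tmp_path):
        fit = fit_ols(toy_design)
        df = fit_to_frame(fit)
        path = tmp_path / "fit.csv"
        df.to_csv(path, index=False)
        back = coefficients_from_frame(pd.read_csv(path))
        for c, b in fit.coefficients.items():
            assert back[c] == pytest.approx(b)

    @pytest.mark.parametrize("model", ["structural_wls", "sequence_wls",
                                       "structural_ols_white"])
    def test_published_tables_obey_se_relation(self, model):
        """se = |beta| / |t| must be positive and finite for every row of
        the published coefficient tables."""
        from oglyc_lpm import reference
        df = reference.load_model(model)
        tcol = [c for c in df.columns if c != "variable" and c != "beta"][0]
        se = df["beta"].abs() / df[tcol]
        assert (se > 0).all() and np.isfinite(se).all()
        assert np.allclose(df["beta"].abs() / se, df[tcol])

    def test_structural_table_variable_count(self):
        from oglyc_lpm import reference
        df = reference.load_model("structural_wls")
        assert len(df) == 86                      # intercept + 85 predictors
        assert (df["variable"] == "intercept").sum() == 1
        for name in ("pos", "ASA_zero", "II", "II´", "Helix", "Beta Bridges",
                     "Beta Hairpin", "Beta Hairpin Strand", "phi"):
            assert name in set(df["variable"])
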