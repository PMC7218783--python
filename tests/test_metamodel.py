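"""Tests for the response-surface metamodel, ANOVA and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edsimopt import (
    ResponseSurfaceRegressor,
    adjusted_r2,
    full_factorial,
    select_interaction_order,
    select_terms,
    summary_reconstruction,
)
from edsimopt.metamodel import candidate_terms, term_label
from edsimopt.reference import (
    REFERENCE_ANOVA_P_VALUES,
    REFERENCE_COEFFICIENTS,
    REFERENCE_DIAGNOSTICS,
)


def multilinear(X, coefs):
    """Independent evaluation of b0 + sum b_j prod_{i in j} x_i."""
    y = np.full(X.shape[0], coefs.get((), 0.0))
    for term, b in coefs.items():
        if term:
            y = y + b * np.prod(X[:, list(term)], axis=1)
    return y


GEN_COEFS = {(): 3.0, (0,): -1.2, (2,): 0.4, (4,): -0.8, (0, 4): 0.25, (1, 2, 4): -0.1}


class TestFit:
    def test_exact_interpolation_of_noise_free_multilinear(self):
        X = full_factorial(5).rows
        y = multilinear(X, GEN_COEFS)
        fit = ResponseSurfaceRegressor(max_order=3).fit(X, y)
        got = fit.coefficients()
        for term in candidate_terms(5, 3):
            assert got[term] == pytest.approx(GEN_COEFS.get(term, 0.0), abs=1e-10)
        assert got[()] == pytest.approx(3.0, abs=1e-10)

    def test_saturated_two_factor_fit_has_zero_residual(self):
        X = full_factorial(2).rows
        y = np.array([1.0, 4.0, 2.0, 7.0])
        fit = ResponseSurfaceRegressor(max_order=2).fit(X, y)
        assert fit.residual_ss_ == pytest.approx(0.0, abs=1e-20)
        assert fit.r2_ == pytest.approx(1.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(k=st.integers(2, 5), seed=st.integers(0, 10**6))
    def test_least_squares_equals_contrast_averages(self, k, seed):
        # independent oracle: b_j = (1/n) sum_i x_ij y_i on any 2^k design
        rng = np.random.default_rng(seed)
        X = full_factorial(k).rows
        y = rng.normal(size=X.shape[0])
        order = min(3, k)
        fit = ResponseSurfaceRegressor(max_order=order).fit(X, y)
        n = X.shape[0]
        for term, b in fit.coefficients().items():
            contrast = np.prod(X[:, list(term)], axis=1) if term else np.ones(n)
            assert b == pytest.approx(float(contrast @ y) / n, abs=1e-10)

    def test_rank_deficient_matrix_names_collinear_terms(self):
        X = full_factorial(2).rows
        X3 = np.column_stack([X, X[:, 0]])  # third factor duplicates the first
        y = np.arange(4.0)
        with pytest.raises(ValueError, match="X1"):
            ResponseSurfaceRegressor(max_order=1).fit(X3, y)

    def test_more_terms_than_runs_rejected(self):
        X = full_factorial(2).rows
        with pytest.raises(ValueError):
            ResponseSurfaceRegressor(
                terms=[(0,), (1,), (0, 1), (2,)]
            ).fit(np.column_stack([X, X[:, 0] * X[:, 1]]), np.arange(4.0))


class TestAnova:
    def _noisy_fit(self, seed=0, sigma=0.05):
        rng = np.random.default_rng(seed)
        X = full_factorial(5).rows
        y = multilinear(X, GEN_COEFS) + rng.normal(0, sigma, X.shape[0])
        return ResponseSurfaceRegressor(max_order=3).fit(X, y)

    def test_sums_of_squares_are_additive(self):
        fit = self._noisy_fit()
        table = fit.anova()
        terms_ss = table.frame.query("term != 'Model'")["sum_of_squares"].sum()
        assert terms_ss + fit.residual_ss_ == pytest.approx(
            fit.total_ss_, rel=1e-8
        )

    def test_term_ss_equals_n_times_coefficient_squared(self):
        fit = self._noisy_fit(seed=3)
        table = fit.anova().frame.query("term != 'Model'")
        n = 32
        for _, row in table.iterrows():
            assert row["sum_of_squares"] == pytest.approx(
                n * row["coefficient"] ** 2, rel=1e-10
            )

    def test_zero_noise_saturated_fit_flags_degenerate_diagnostics(self):
        X = full_factorial(2).rows
        y = np.array([1.0, 4.0, 2.0, 7.0])
        table = ResponseSurfaceRegressor(max_order=2).fit(X, y).anova()
        assert table.degenerate
        assert np.isnan(table.frame["f_value"]).all()

    def test_f_and_p_match_scipy_reference(self):
        from scipy import stats

        fit = self._noisy_fit(seed=5)
        table = fit.anova()
        df_res = table.residual_df
        ms_res = table.residual_ss / df_res
        row = table.frame.query("term == 'X1'").iloc[0]
        f = row["sum_of_squares"] / ms_res
        assert row["f_value"] == pytest.approx(f)
        assert row["p_value"] == pytest.approx(float(stats.f.sf(f, 1, df_res)))


class TestAdjustedR2:
    def test_reference_panel_value(self):
        assert adjusted_r2(0.9419, 32, 25) == pytest.approx(0.70, abs=0.005)

    def test_perfect_fit_is_fixed_point(self):
        assert adjusted_r2(1.0, 32, 25) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r2=st.floats(0, 1),
        n=st.integers(5, 200),
        p=st.integers(1, 3),
    )
    def test_never_exceeds_r2(self, r2, n, p):
        assert adjusted_r2(r2, n, p) <= r2 + 1e-12

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, 10, 9)


class TestPress:
    def test_perfect_fit_gives_zero(self):
        X = full_factorial(3).rows
        y = multilinear(X, {(): 1.0, (0,): 0.5})
        fit = ResponseSurfaceRegressor(max_order=1).fit(X, y)
        assert fit.press() == pytest.approx(0.0, abs=1e-20)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(k=st.integers(3, 5), seed=st.integers(0, 10**6))
    def test_leverage_path_equals_closed_form_on_balanced_designs(self, k, seed):
        # independent hat-matrix oracle: H = Z (Z'Z)^-1 Z'
        rng = np.random.default_rng(seed)
        X = full_factorial(k).rows
        y = rng.normal(size=X.shape[0])
        fit = ResponseSurfaceRegressor(max_order=min(2, k - 1)).fit(X, y)
        Z = fit.model_matrix_
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        e = y - fit.fitted_values_
        oracle = float(np.sum((e / (1 - np.diag(H))) ** 2))
        assert fit.press() == pytest.approx(oracle, rel=1e-9)
        p_prime = len(fit.terms_) + 1
        closed = fit.residual_ss_ / (1 - p_prime / len(y)) ** 2
        assert fit.press() == pytest.approx(closed, rel=1e-9)


class TestAdequatePrecision:
    def _table_fit(self, scale=1.0):
        rng = np.random.default_rng(11)
        X = full_factorial(4).rows
        y = scale * (multilinear(X, {(): 2.0, (0,): 1.0, (3,): -0.5})
                     + rng.normal(0, 0.2, X.shape[0]))
        return ResponseSurfaceRegressor(max_order=1).fit(X, y)

    def test_invariant_under_response_scaling(self):
        assert self._table_fit(1.0).adequate_precision() == pytest.approx(
            self._table_fit(7.0).adequate_precision()
        )

    def test_constant_responses_are_degenerate(self):
        X = full_factorial(3).rows
        fit = ResponseSurfaceRegressor(max_order=1).fit(X, np.full(8, 5.0))
        with pytest.raises(ValueError):
            fit.adequate_precision()

    def test_matches_direct_formula_evaluation(self):
        fit = self._table_fit()
        n = len(fit.y_)
        p_prime = len(fit.terms_) + 1
        ms_res = fit.residual_ss_ / fit.residual_df_
        yhat = fit.fitted_values_
        expected = (yhat.max() - yhat.min()) / np.sqrt(p_prime * ms_res / n)
        assert fit.adequate_precision() == pytest.approx(expected)


class TestReduce:
    def test_reference_panel_reduction_recovers_reduced_equation_terms(self):
        # keep p < 0.05, force the X2, X3, X4 mains
        retained = select_terms(
            REFERENCE_ANOVA_P_VALUES, 0.05, forced_terms=[(1,), (2,), (3,)]
        )
        expected = {t for t in REFERENCE_COEFFICIENTS if t}
        assert set(retained) == expected
        assert len(retained) == 9

    def test_alpha_one_keeps_everything(self):
        retained = select_terms(REFERENCE_ANOVA_P_VALUES, 1.0, [])
        assert set(retained) == set(REFERENCE_ANOVA_P_VALUES)

    def test_alpha_zero_keeps_only_forced(self):
        assert select_terms(REFERENCE_ANOVA_P_VALUES, 0.0, []) == []

    def test_refit_after_reduction_and_idempotence(self):
        rng = np.random.default_rng(2)
        X = full_factorial(5).rows
        y = multilinear(X, GEN_COEFS) + rng.normal(0, 0.05, 32)
        fit = ResponseSurfaceRegressor(max_order=3).fit(X, y)
        red = fit.reduce(alpha=0.05, forced_terms=[(1,)])
        assert (1,) in red.terms_
        red2 = red.reduce(alpha=0.05, forced_terms=[(1,)])
        assert red2.terms_ == red.terms_
        assert np.allclose(red2.coef_, red.coef_)

    def test_unknown_forced_term_rejected(self):
        with pytest.raises(ValueError):
            select_terms(REFERENCE_ANOVA_P_VALUES, 0.05, [(0, 1, 2, 3)])


class TestPredict:
    def test_center_point_returns_intercept(self):
        X = full_factorial(5).rows
        fit = ResponseSurfaceRegressor(max_order=3).fit(X, multilinear(X, GEN_COEFS))
        assert fit.predict(np.zeros((1, 5)))[0] == pytest.approx(3.0)

    def test_affine_in_each_coordinate(self):
        X = full_factorial(5).rows
        fit = ResponseSurfaceRegressor(max_order=3).fit(X, multilinear(X, GEN_COEFS))
        base = np.array([0.3, -0.5, 0.2, 0.9, -0.1])
        pts = np.array([base, base, base])
        pts[:, 0] = [-1.0, 0.0, 1.0]
        lo, mid, hi = fit.predict(pts)
        assert mid == pytest.approx((lo + hi) / 2, abs=1e-12)

    def test_extrapolation_warns_but_computes(self):
        X = full_factorial(2).rows
        fit = ResponseSurfaceRegressor(max_order=1).fit(X, np.arange(4.0))
        with pytest.warns(UserWarning, match="extrapolation"):
            out = fit.predict([[2.0, 0.0]])
        assert np.isfinite(out[0])


class TestParameterRecovery:
    def test_unbiased_estimates_with_correct_sampling_error(self):
        """Known surface + Gaussian noise over 200 replicated 2^5 designs."""
        sigma = 0.3
        X = full_factorial(5).rows
        n = X.shape[0]
        truth = multilinear(X, GEN_COEFS)
        rng = np.random.default_rng(99)
        reps = 200
        track = [(0,), (4,), (0, 4), (1, 2, 4)]
        estimates = {t: [] for t in track}
        for _ in range(reps):
            fit = ResponseSurfaceRegressor(max_order=3).fit(
                X, truth + rng.normal(0, sigma, n)
            )
            coefs = fit.coefficients()
            for t in track:
                estimates[t].append(coefs[t])
        se_theory = sigma / np.sqrt(n)
        for t in track:
            est = np.asarray(estimates[t])
            assert abs(est.mean() - GEN_COEFS.get(t, 0.0)) < 3 * se_theory / np.sqrt(reps)
            assert abs(est.std(ddof=1) - se_theory) / se_theory < 0.15


class TestModelSelection:
    def test_lowest_significant_interaction_order_is_chosen(self):
        rng = np.random.default_rng(4)
        X = full_factorial(5).rows
        y = multilinear(X, {(): 2.0, (0,): 1.5, (4,): -1.0}) + rng.normal(0, 0.1, 32)
        order, pvals = select_interaction_order(X, y, alpha=0.05)
        assert order == 1
        assert pvals[1] < 0.05


class TestSummaryReconstruction:
    def test_reference_panel_anchors(self):
        d = REFERENCE_DIAGNOSTICS
        rec = summary_reconstruction(
            d["ss_model"], d["r2"], int(d["n_obs"]), int(d["n_terms"])
        )
        assert rec["model_f"] == pytest.approx(3.89, abs=0.01)
        assert rec["standard_error"] == pytest.approx(0.023, abs=0.0005)
        assert rec["press"] == pytest.approx(2.94, rel=0.01)
        assert rec["adjusted_r2"] == pytest.approx(0.70, abs=0.005)

    def test_term_labels(self):
        assert term_label(()) == "Intercept"
        assert term_label((0, 4)) == "X1X5"
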