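"""Plain and Firth-penalized logistic regression against independent oracles.

Oracles: closed-form 2x2 log odds ratios (Haldane-corrected for the Firth
engine), direct grid maximization of the penalized likelihood, and
statsmodels' Logit for the maximum-likelihood engine.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

from rarecomp.firth import (
    INTERCEPT,
    DesignSpec,
    FitResult,
    SeparationError,
    fit_firth,
    fit_logistic,
    penalized_lrt,
    wald_test,
)


def pll(y, X, beta):
    """Independent penalized log-likelihood: l(beta) + 0.5 log det X'WX."""
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1.0 - pi)
    sign, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def grid_argmax_1d(y, X, lo, hi, n=20001):
    grid = np.linspace(lo, hi, n)
    vals = [pll(y, X, np.array([b])) for b in grid]
    return grid[int(np.argmax(vals))], max(vals)


def two_by_two_cohort(a, b, c, d):
    """Events/non-events by arm: (a, b) at x=1, (c, d) at x=0."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1] * (a + b) + [0] * (c + d)
    return pd.DataFrame({"event": y, "x": [float(v) for v in x]})


DESIGN_X = DesignSpec(outcome="event", treatment="x")


class TestLogisticMLE:
    def test_intercept_only_sample_log_odds(self):
        from rarecomp.firth import _fit_core

        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = _fit_core(y, np.ones((100, 1)), [INTERCEPT], engine="mle")
        assert fit.params[INTERCEPT] == pytest.approx(math.log(25 / 75), abs=1e-6)

    def test_two_by_two_closed_form(self):
        fit = fit_logistic(two_by_two_cohort(3, 7, 9, 1), DESIGN_X)
        assert fit.params["x"] == pytest.approx(math.log((3 * 1) / (7 * 9)), abs=1e-6)
        assert fit.converged and not fit.separation_flag

    def test_matches_statsmodels_on_simulated_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 800
        x = rng.binomial(1, 0.3, n).astype(float)
        age = rng.normal(0, 1, n)
        eta = -1.5 + 0.6 * x + 0.3 * age
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        cohort = pd.DataFrame({"event": y, "x": x, "age": age})
        fit = fit_logistic(cohort, DesignSpec("event", "x", ("age",)))
        X = np.column_stack([np.ones(n), x, age])
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)

    def test_complete_separation_flagged(self, separation_cohort):
        fit = fit_logistic(separation_cohort, DESIGN_X)
        assert fit.separation_flag and not fit.converged

    def test_single_class_outcome_raises(self):
        cohort = pd.DataFrame({"event": [0] * 10, "x": [0, 1] * 5})
        with pytest.raises(SeparationError):
            fit_logistic(cohort, DESIGN_X)

    def test_constant_column_named_in_error(self):
        cohort = pd.DataFrame({"event": [0, 1] * 5, "x": [1, 0] * 5, "k": [3.0] * 10})
        with pytest.raises(ValueError, match="'k'"):
            fit_logistic(cohort, DesignSpec("event", "x", ("k",)))

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        cohort = pd.DataFrame(
            {"event": rng.binomial(1, 0.4, 30), "x": rng.binomial(1, 0.5, 30).astype(float),
             "a": a, "b": 2.0 * a}
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_firth(cohort, DesignSpec("event", "x", ("a", "b")))


class TestFirth:
    @pytest.mark.parametrize("k, n", [(0, 10), (3, 20), (25, 100), (100, 100)])
    def test_intercept_only_jeffreys_mode(self, k, n):
        # closed form: penalized-likelihood event probability (k + 1/2) / (n + 1)
        from rarecomp.firth import _fit_core

        expected = math.log((k + 0.5) / (n - k + 0.5))
        y = np.array([1.0] * k + [0.0] * (n - k))
        f0 = _fit_core(y, np.ones((n, 1)), [INTERCEPT], engine="firth")
        assert f0.params[INTERCEPT] == pytest.approx(expected, abs=1e-6)
        # grid oracle agrees
        b_grid, _ = grid_argmax_1d(y, np.ones((n, 1)), expected - 1.0, expected + 1.0)
        assert f0.params[INTERCEPT] == pytest.approx(b_grid, abs=1e-3)

    def test_two_by_two_haldane_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, 4)
            # keep both arms populated
            if a + b == 0 or c + d == 0:
                continue
            fit = fit_firth(two_by_two_cohort(a, b, c, d), DESIGN_X)
            expected = math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
            assert fit.params["x"] == pytest.approx(expected, abs=1e-6)

    def test_finite_under_complete_separation(self, separation_cohort):
        fit = fit_firth(separation_cohort, DESIGN_X)
        assert fit.converged and not fit.separation_flag
        assert np.isfinite(fit.params).all()
        assert fit.params["x"] == pytest.approx(math.log(25.0), abs=1e-6)  # Haldane

    def test_finite_on_single_class_outcome(self):
        cohort = pd.DataFrame({"event": [0] * 12, "x": [0, 1] * 6})
        fit = fit_firth(cohort, DESIGN_X)
        assert fit.converged and np.isfinite(fit.params).all()

    def test_agrees_with_mle_on_abundant_balanced_data(self):
        rng = np.random.default_rng(9)
        n = 10_000
        x = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, np.where(x == 1, 0.35, 0.3)).astype(float)
        cohort = pd.DataFrame({"event": y, "x": x})
        f = fit_firth(cohort, DESIGN_X)
        m = fit_logistic(cohort, DESIGN_X)
        assert abs(f.params["x"] - m.params["x"]) < 0.02
        assert abs(f.params[INTERCEPT] - m.params[INTERCEPT]) < 0.02

    def test_arm_relabel_negates_treatment_coefficient(self):
        rng = np.random.default_rng(23)
        n = 400
        x = rng.binomial(1, 0.4, n).astype(float)
        y = rng.binomial(1, np.where(x == 1, 0.1, 0.05)).astype(float)
        a = fit_firth(pd.DataFrame({"event": y, "x": x}), DESIGN_X)
        b = fit_firth(pd.DataFrame({"event": y, "x": 1.0 - x}), DESIGN_X)
        assert a.params["x"] == pytest.approx(-b.params["x"], abs=1e-7)


class TestWald:
    def _fit(self, est, se):
        return FitResult(
            engine="mle",
            params=pd.Series({"x": est}),
            bse=pd.Series({"x": se}),
            loglik=0.0, converged=True, n_iter=3,
        )

    def test_estimate_at_null_gives_p_one(self):
        t = wald_test(self._fit(0.3, 0.1), "x", null_value=0.3)
        assert t.p_value == pytest.approx(1.0)
        assert t.statistic == pytest.approx(0.0)

    def test_normal_reference(self):
        t = wald_test(self._fit(1.96, 1.0), "x")
        assert t.p_value == pytest.approx(0.05, abs=1e-3)
        t3 = wald_test(self._fit(-0.9, 0.3), "x")
        assert t3.p_value == pytest.approx(2 * norm.cdf(-3.0), rel=1e-10)

    def test_one_sided(self):
        t = wald_test(self._fit(-0.6, 0.3), "x", sided="less")
        assert t.p_value == pytest.approx(norm.cdf(-2.0), rel=1e-10)
        t2 = wald_test(self._fit(-0.6, 0.3), "x", sided="greater")
        assert t2.p_value == pytest.approx(norm.sf(-2.0), rel=1e-10)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(self._fit(0.5, 0.0), "x")


class TestPenalizedLRT:
    def test_null_at_estimate_gives_zero_statistic(self):
        cohort = two_by_two_cohort(4, 16, 9, 21)
        fit = fit_firth(cohort, DESIGN_X)
        t = penalized_lrt(cohort, DESIGN_X, "x", null_value=float(fit.params["x"]))
        assert t.statistic == pytest.approx(0.0, abs=1e-8)
        assert t.p_value == pytest.approx(1.0, abs=1e-4)

    def test_chi2_reference(self):
        # a statistic of 3.84 must map to p ~ 0.05; check via the inverse
        assert chi2.sf(3.841458820694124, 1) == pytest.approx(0.05)

    def test_statistic_nonnegative_over_random_nulls(self):
        cohort = two_by_two_cohort(5, 45, 20, 130)
        for null in np.linspace(-2.0, 2.0, 9):
            t = penalized_lrt(cohort, DESIGN_X, "x", null_value=float(null))
            assert t.statistic >= 0.0

    def test_separation_fixture_matches_grid_oracle(self, separation_xy):
        y, x = separation_xy
        X = np.column_stack([np.ones(4), x])
        cohort = pd.DataFrame({"event": y.astype(int), "x": x})
        t = penalized_lrt(cohort, DESIGN_X, "x", null_value=0.0)
        # oracle: 2 * (max_{b0,b1} pll - max_{b0; b1=0} pll) by grid search
        grid = np.linspace(-6.0, 6.0, 481)
        full = max(pll(y, X, np.array([b0, b1])) for b0 in grid for b1 in grid)
        constrained = max(pll(y, X, np.array([b0, 0.0])) for b0 in grid)
        assert t.statistic == pytest.approx(2 * (full - constrained), abs=1e-3)
        assert np.isfinite(t.statistic) and 0 < t.p_value < 1

    def test_one_sided_signed_root(self):
        cohort = two_by_two_cohort(3, 47, 20, 80)  # arm 1 has fewer events
        two = penalized_lrt(cohort, DESIGN_X, "x", null_value=0.0, sided="two-sided")
        less = penalized_lrt(cohort, DESIGN_X, "x", null_value=0.0, sided="less")
        greater = penalized_lrt(cohort, DESIGN_X, "x", null_value=0.0, sided="greater")
        # estimate is below the null: the "less" side gets half the two-sided p
        assert less.p_value == pytest.approx(two.p_value / 2, rel=1e-9)
        assert greater.p_value == pytest.approx(1 - two.p_value / 2, rel=1e-9)
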