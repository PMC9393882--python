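"""Conditional logistic likelihood, Newton fit, and Wald inference."""

import numpy as np
import pandas as pd
import pytest

from lagcross import (
    ModelSpec,
    conditional_loglik,
    fit_clr,
    fit_conditional_logit,
    or_ci,
    simulate_strata,
)
from lagcross.clr import (
    CLRError,
    NotConvergedError,
    RankDeficiencyError,
    SeparationError,
)


def brute_force_loglik(beta, X):
    """Direct per-stratum enumeration without log-sum-exp stabilization."""
    beta = np.atleast_1d(beta)
    total = 0.0
    for stratum in X:
        etas = [float(row @ beta) for row in stratum]
        total += etas[0] - np.log(sum(np.exp(e) for e in etas))
    return total


class TestConditionalLoglik:
    def test_null_beta_gives_uniform_within_stratum(self, rng):
        X = rng.normal(size=(37, 4, 2))
        assert conditional_loglik([0.0, 0.0], X) == pytest.approx(37 * np.log(0.25))

    @pytest.mark.parametrize("b", [-1.5, 0.3, 2.0])
    def test_single_stratum_closed_form(self, b):
        X = np.array([[1.0, 0.0, 0.0, 0.0]])  # case exposed, 3 unexposed controls
        assert conditional_loglik([b], X) == pytest.approx(b - np.log(np.exp(b) + 3))

    def test_matches_brute_force_enumeration(self, rng):
        X = rng.normal(size=(20, 4, 3))
        beta = rng.normal(size=3)
        assert conditional_loglik(beta, X) == pytest.approx(
            brute_force_loglik(beta, X), rel=1e-12)

    def test_stratum_too_small_errors(self):
        with pytest.raises(CLRError):
            conditional_loglik([0.0], np.ones((3, 1, 1)))


class TestFitting:
    def test_single_parameter_matches_grid_search(self, rng):
        X = simulate_strata(300, 1.4, rng) / 10.0
        fit = fit_conditional_logit(X[:, :, None], terms=("exposure",))
        grid = np.linspace(fit.beta[0] - 0.5, fit.beta[0] + 0.5, 2001)
        lls = [conditional_loglik([b], X[:, :, None]) for b in grid]
        assert abs(fit.beta[0] - grid[int(np.argmax(lls))]) < 1e-3

    def test_maximum_dominates_random_draws(self, rng):
        X = rng.normal(size=(150, 4, 2))
        fit = fit_conditional_logit(X)
        ll_hat = fit.loglik
        for _ in range(200):
            assert conditional_loglik(fit.beta + rng.normal(scale=0.5, size=2), X) <= ll_hat + 1e-9

    def test_invariant_to_stratum_constant_shift(self, rng):
        X = simulate_strata(200, 1.5, rng)[:, :, None]
        shifted = X + rng.normal(size=(200, 1, 1)) * 50.0
        f0 = fit_conditional_logit(X)
        f1 = fit_conditional_logit(shifted)
        assert f1.beta[0] == pytest.approx(f0.beta[0], rel=1e-8)
        assert f1.loglik == pytest.approx(f0.loglik, rel=1e-10)

    def test_aic_and_lr_consistency(self, rng):
        X = simulate_strata(400, 1.6, rng)[:, :, None] / 10.0
        fit = fit_conditional_logit(X)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2)
        assert fit.loglik <= 0 and fit.loglik >= fit.loglik_null
        assert fit.lr_stat >= 0

    def test_identical_exposures_flat_likelihood(self):
        X = np.full((50, 4, 1), 3.0)
        with pytest.raises(CLRError):
            fit_conditional_logit(X)

    def test_complete_separation_detected(self):
        # case always strictly largest: likelihood maximized at +infinity
        X = np.tile(np.array([2.0, 1.0, 0.0, -1.0]), (80, 1))[:, :, None]
        with pytest.raises(SeparationError):
            fit_conditional_logit(X)

    def test_constant_column_dropped_and_named(self, rng):
        X = rng.normal(size=(60, 4, 2))
        X[:, :, 1] = 7.0  # stratum-constant (matched) covariate
        fit = fit_conditional_logit(X, terms=("exposure", "age"))
        assert fit.dropped == ("age",)
        assert fit.terms == ("exposure",)

    def test_rank_deficiency_names_dependent_column(self, rng):
        X = rng.normal(size=(60, 4, 3))
        X[:, :, 2] = 2.0 * X[:, :, 0] - X[:, :, 1]
        with pytest.raises(RankDeficiencyError, match="x2"):
            fit_conditional_logit(X)

    def test_cross_check_against_statsmodels(self, rng):
        """Independent oracle: statsmodels ConditionalLogit on the same strata."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        S = 250
        X = rng.normal(size=(S, 4, 2))
        X = np.concatenate([X, rng.normal(size=(S, 4, 1))], axis=2)
        # draw cases from a model with real effects
        beta_true = np.array([0.4, -0.3, 0.2])
        eta = X @ beta_true
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((S, 1))
        case = (p.cumsum(axis=1) > u).argmax(axis=1)
        idx = np.arange(S)
        X[idx, 0], X[idx, case] = X[idx, case].copy(), X[idx, 0].copy()

        fit = fit_conditional_logit(X)
        y = np.zeros((S, 4)); y[:, 0] = 1
        groups = np.repeat(np.arange(S), 4)
        sm_fit = ConditionalLogit(y.ravel(), X.reshape(-1, 3), groups=groups).fit(disp=0)
        # statsmodels' BFGS stops at a looser gradient tolerance than the
        # Newton fit here, so compare at its precision
        np.testing.assert_allclose(fit.beta, sm_fit.params, rtol=1e-3, atol=1e-4)
        np.testing.assert_allclose(fit.se, sm_fit.bse, rtol=1e-3)
        assert fit.loglik >= sm_fit.llf - 1e-8


class TestORScaling:
    def test_wald_interval_arithmetic(self, rng):
        X = simulate_strata(500, 1.0, rng)[:, :, None]
        fit = fit_conditional_logit(X, terms=("exposure",))
        # rebuild a fit-like check with forced beta/se through or_ci arithmetic
        fit.beta = np.array([0.0]); fit.se = np.array([0.1])
        o, lo, hi, p = or_ci(fit, "exposure")
        assert o == 1.0
        assert lo == pytest.approx(np.exp(-1.959964 * 0.1), rel=1e-6)  # ~0.822
        assert hi == pytest.approx(np.exp(+1.959964 * 0.1), rel=1e-6)  # ~1.217
        assert p == pytest.approx(1.0)

    def test_scale_log_linearity(self, rng):
        X = simulate_strata(300, 1.5, rng)[:, :, None]
        fit = fit_conditional_logit(X)
        o1, lo1, hi1, p1 = or_ci(fit, 0, scale=1.0)
        o10, lo10, hi10, p10 = or_ci(fit, 0, scale=10.0)
        assert o10 == pytest.approx(o1**10, rel=1e-10)
        assert p10 == pytest.approx(p1)

    def test_requires_convergence(self, rng):
        X = simulate_strata(50, 1.2, rng)[:, :, None]
        fit = fit_conditional_logit(X)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            or_ci(fit, 0)


def strata_frame(X, extra=None):
    """Long-format stratum table for a (S, 4) exposure array (case first)."""
    S = len(X)
    rows = []
    for s in range(S):
        for j in range(4):
            rows.append({
                "stratum_id": s, "is_case": int(j == 0), "PMB_l0": X[s, j],
                **({} if extra is None else {k: v[s, j] for k, v in extra.items()}),
            })
    return pd.DataFrame(rows)


class TestDataFrameInterface:
    def test_fit_clr_matches_low_level(self, rng):
        X = simulate_strata(400, 1.5, rng)
        df = strata_frame(X)
        fit = fit_clr(ModelSpec("PMB", "0", scale=10.0), df)
        low = fit_conditional_logit((X / 10.0)[:, :, None])
        assert fit.beta[0] == pytest.approx(low.beta[0], rel=1e-8)

    def test_aic_penalizes_noise_improves_with_signal(self, rng):
        X = simulate_strata(600, 1.8, rng)
        noise = rng.normal(size=(600, 4))
        df = strata_frame(X, extra={"noise": noise})
        base = fit_clr(ModelSpec("PMB", "0", confounders=()), df)
        plus_noise = fit_clr(ModelSpec("PMB", "0", confounders=("noise",)), df)
        # pure noise: expected AIC increase (allow the chi2 slack of one draw)
        assert plus_noise.aic > base.aic - 4.0
        # the exposure signal itself must beat the null model decisively
        assert base.aic < -2.0 * base.loglik_null
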