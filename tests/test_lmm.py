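"""Mixed-model core against dense-matrix oracles and statsmodels."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from wcie.lmm import blup, fit_lmm_arrays, sample_parameters
from wcie.lmm import RankDeficientError, UnknownSubjectError

from conftest import make_longitudinal


def dense_loglik(y, X, Z, ids, beta, sigma, B):
    """Marginal Gaussian log-likelihood from per-subject dense covariances."""
    ll = 0.0
    for i in np.unique(ids):
        m = ids == i
        V = Z[m] @ B @ Z[m].T + sigma**2 * np.eye(m.sum())
        ll += sps.multivariate_normal.logpdf(y[m], X[m] @ beta, V)
    return ll


@pytest.fixture(scope="module")
def fitted():
    y, X, Z, ids, *_ = make_longitudinal(seed=3)
    return (y, X, Z, ids), fit_lmm_arrays(y, X, Z, ids)


class TestAgainstDenseOracle:
    def test_loglik_matches_dense_formula(self, fitted):
        (y, X, Z, ids), fit = fitted
        dense = dense_loglik(y, X, Z, ids, fit.fixed_estimates, fit.resid_sd, fit.re_cov)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_beta_is_gls_solution(self, fitted):
        (y, X, Z, ids), fit = fitted
        # beta_hat = (X'V^-1X)^-1 X'V^-1 y with the fitted covariance
        Vi_X, Vi_y = [], []
        for i in np.unique(ids):
            m = ids == i
            V = Z[m] @ fit.re_cov @ Z[m].T + fit.resid_sd**2 * np.eye(m.sum())
            Vi = np.linalg.inv(V)
            Vi_X.append(X[m].T @ Vi @ X[m])
            Vi_y.append(X[m].T @ Vi @ y[m])
        beta = np.linalg.solve(sum(Vi_X), sum(Vi_y))
        np.testing.assert_allclose(fit.fixed_estimates, beta, atol=1e-8)
        # and the reported covariance is the GLS covariance
        np.testing.assert_allclose(fit.fixed_vcov, np.linalg.inv(sum(Vi_X)), rtol=1e-6)

    def test_blups_match_dense_formula(self, fitted):
        (y, X, Z, ids), fit = fitted
        for i in [0, 7, 31]:
            m = ids == i
            V = Z[m] @ fit.re_cov @ Z[m].T + fit.resid_sd**2 * np.eye(m.sum())
            expected = fit.re_cov @ Z[m].T @ np.linalg.solve(
                V, y[m] - X[m] @ fit.fixed_estimates)
            np.testing.assert_allclose(blup(fit, i), expected, atol=1e-8)

    def test_blup_unknown_subject(self, fitted):
        _, fit = fitted
        with pytest.raises(UnknownSubjectError):
            blup(fit, "nobody")


class TestAgainstStatsmodels:
    def test_ml_solution_at_least_as_good(self):
        y, X, Z, ids, *_ = make_longitudinal(seed=11, n=80)
        fit = fit_lmm_arrays(y, X, Z, ids)
        res = sm.regression.mixed_linear_model.MixedLM(
            y, X, groups=ids, exog_re=Z).fit(reml=False)
        # both maximize the same ML criterion
        assert fit.loglik >= res.llf - 1e-3
        np.testing.assert_allclose(fit.fixed_estimates, res.fe_params, atol=5e-3)
        assert fit.resid_sd**2 == pytest.approx(res.scale, rel=0.02)
        np.testing.assert_allclose(fit.re_cov, res.cov_re, atol=0.05)


class TestInvariances:
    def test_fixed_column_scaling_invariance(self):
        # multiplying an X column by 1e6 must leave fit and loglik unchanged
        y, X, Z, ids, *_ = make_longitudinal(seed=5)
        fit1 = fit_lmm_arrays(y, X, Z, ids)
        X2 = X.copy()
        X2[:, 2] *= 1e6
        fit2 = fit_lmm_arrays(y, X2, Z, ids)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-5)
        assert fit2.fixed_estimates[2] * 1e6 == pytest.approx(
            fit1.fixed_estimates[2], rel=1e-5)

    def test_random_column_scaling_invariance(self):
        y, X, Z, ids, *_ = make_longitudinal(seed=5)
        fit1 = fit_lmm_arrays(y, X, Z, ids)
        Z2 = Z.copy()
        Z2[:, 1] *= 100.0
        fit2 = fit_lmm_arrays(y, X, Z2, ids)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-4)
        assert fit2.re_cov[1, 1] * 100.0**2 == pytest.approx(fit1.re_cov[1, 1], rel=1e-3)

    def test_rank_deficient_design_raises_with_suspects(self):
        y, X, Z, ids, *_ = make_longitudinal(seed=6)
        X2 = np.column_stack([X, X[:, 1]])  # duplicate the time column
        with pytest.raises(RankDeficientError):
            fit_lmm_arrays(y, X2, Z, ids)


class TestParameterRecovery:
    def test_recovers_generating_values(self):
        y, X, Z, ids, beta, B, sigma = make_longitudinal(seed=42, n=400)
        fit = fit_lmm_arrays(y, X, Z, ids)
        np.testing.assert_allclose(fit.fixed_estimates, beta, atol=0.15)
        assert fit.resid_sd == pytest.approx(sigma, abs=0.05)
        np.testing.assert_allclose(fit.re_cov, B, atol=0.25)
        assert fit.converged


class TestSampling:
    @pytest.fixture(scope="class")
    def fit(self):
        y, X, Z, ids, *_ = make_longitudinal(seed=9, n=120)
        return fit_lmm_arrays(y, X, Z, ids, compute_vc_vcov=True)

    def test_shapes_and_validity(self, fit):
        draws = sample_parameters(fit, 200, seed=1)
        assert draws.beta.shape == (200, fit.fixed_estimates.size)
        assert np.all(draws.sigma > 0)
        eigs = np.linalg.eigvalsh(draws.re_cov)
        assert np.all(eigs > -1e-10)  # every drawn covariance is PSD

    def test_deterministic_given_seed(self, fit):
        d1 = sample_parameters(fit, 5, seed=7)
        d2 = sample_parameters(fit, 5, seed=7)
        np.testing.assert_array_equal(d1.raw, d2.raw)

    def test_beta_draw_spread_matches_gls_vcov(self, fit):
        draws = sample_parameters(fit, 4000, seed=3)
        emp = np.cov(draws.beta.T)
        np.testing.assert_allclose(emp, fit.fixed_vcov, rtol=0.15, atol=1e-4)

    def test_draws_stay_in_likelihood_support(self, fit):
        # a 1-SD parameter draw should cost only a few log-likelihood units;
        # this guards the calibration of the variance-parameter covariance
        from wcie.lmm import _loglik_at, _vc_unpack

        draws = sample_parameters(fit, 100, seed=5)
        q = fit.q
        drops = []
        for m in range(100):
            s, _, L = _vc_unpack(draws.raw[m, fit.fixed_estimates.size:], q)
            ll = _loglik_at(fit.stats, fit.fixed_estimates * fit.x_scale, s, L)
            drops.append(fit.loglik - ll)
        assert np.median(drops) < 30.0

    def test_requires_vcov(self):
        y, X, Z, ids, *_ = make_longitudinal(seed=10)
        fit = fit_lmm_arrays(y, X, Z, ids, compute_vc_vcov=False)
        assert fit.vc_vcov is None
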