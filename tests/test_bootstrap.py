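"""Parametric bootstrap of the total stage-2 covariance (Eq.-12 style)."""

import numpy as np
import pytest

from wcie.bases import BasisSpec, NATURAL_CUBIC
from wcie.bootstrap import bootstrap_total_variance, trajectory_with_bootstrap_ci
from wcie.exposure import ExposureHistoryModel
from wcie.history import history_covariates
from wcie.outcome import fit_outcome_model

WEIGHT = BasisSpec(NATURAL_CUBIC, (-12.0,), (-24.0, 0.0), include_intercept=True)


@pytest.fixture(scope="module")
def pieces(small_cohort, fitted_exposure, predicted):
    _, outcome, _ = small_cohort
    H = history_covariates(predicted, WEIGHT)
    fit, info = fit_outcome_model(outcome, H, ("age0", "education"), True)
    return outcome, fit, info


class TestTotalVariance:
    def test_single_draw_returns_intra_variance_exactly(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        boot = bootstrap_total_variance(
            fitted_exposure, outcome, WEIGHT, fit, n_draws=1, seed=0,
            confounders=("age0", "education"), include_v0=True)
        # with M = 1 the between term is exactly zero
        np.testing.assert_array_equal(boot.V_between, np.zeros_like(boot.V_between))
        np.testing.assert_array_equal(boot.V_tot, boot.V_intra)

    def test_total_is_intra_plus_between(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        boot = bootstrap_total_variance(
            fitted_exposure, outcome, WEIGHT, fit, n_draws=12, seed=1,
            confounders=("age0", "education"), include_v0=True)
        np.testing.assert_allclose(boot.V_tot, boot.V_intra + boot.V_between)
        assert boot.n_effective + boot.n_failed == 12
        # the between-draw scatter must be PSD
        assert np.linalg.eigvalsh(boot.V_between).min() > -1e-10

    def test_deterministic_given_seed(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        kw = dict(confounders=("age0", "education"), include_v0=True)
        b1 = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                      n_draws=6, seed=42, **kw)
        b2 = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                      n_draws=6, seed=42, **kw)
        np.testing.assert_array_equal(b1.phi_draws, b2.phi_draws)

    def test_fixed_param_set_varies_only_beta(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        kw = dict(confounders=("age0", "education"), include_v0=True)
        b_all = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                         n_draws=8, seed=3, param_set="all", **kw)
        b_fix = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                         n_draws=8, seed=3, param_set="fixed", **kw)
        # both produce valid totals; they generally differ
        assert b_all.V_tot.shape == b_fix.V_tot.shape
        assert not np.allclose(b_all.V_tot, b_fix.V_tot)

    def test_mminus1_denominator_scales_between(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        kw = dict(confounders=("age0", "education"), include_v0=True, seed=5,
                  n_draws=6)
        bM = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                      denominator="M", **kw)
        bM1 = bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                       denominator="M-1", **kw)
        M = bM.n_effective
        np.testing.assert_allclose(bM1.V_between * (M - 1), bM.V_between * M,
                                   rtol=1e-10)


class TestValidation:
    def test_requires_positive_draws(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        with pytest.raises(ValueError, match="n_draws"):
            bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit, n_draws=0)

    def test_requires_stage1_vcov(self, small_cohort, pieces):
        exposure, outcome, _ = small_cohort
        _, fit, info = pieces
        bare = ExposureHistoryModel(compute_vcov=False).fit(exposure)
        with pytest.raises(ValueError, match="compute_vcov"):
            bootstrap_total_variance(bare, outcome, WEIGHT, fit, n_draws=2)

    def test_bad_denominator_and_param_set(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        with pytest.raises(ValueError, match="denominator"):
            bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                     n_draws=2, denominator="N")
        with pytest.raises(ValueError, match="param_set"):
            bootstrap_total_variance(fitted_exposure, outcome, WEIGHT, fit,
                                     n_draws=2, param_set="some")


class TestTrajectoryCI:
    def test_bootstrap_bands_contain_point_estimates(self, fitted_exposure, pieces):
        outcome, fit, info = pieces
        boot = bootstrap_total_variance(
            fitted_exposure, outcome, WEIGHT, fit, n_draws=10, seed=2,
            confounders=("age0", "education"), include_v0=True)
        grid = np.arange(-24.0, 0.5, 1.0)
        traj = trajectory_with_bootstrap_ci(fit, info, grid, boot)
        assert traj.variance_source == "bootstrap"
        frame = traj.to_frame()
        assert np.all(frame["lo_level"] <= frame["estimate_level"])
        assert np.all(frame["estimate_level"] <= frame["hi_level"])

    def test_bootstrap_variance_not_below_naive(self, fitted_exposure, pieces):
        # Eq. 12 adds stage-1 uncertainty on top of the intra-fit variance,
        # so the total pointwise variance must dominate the naive one
        outcome, fit, info = pieces
        boot = bootstrap_total_variance(
            fitted_exposure, outcome, WEIGHT, fit, n_draws=25, seed=9,
            confounders=("age0", "education"), include_v0=True)
        grid = np.arange(-24.0, 0.5, 1.0)
        from wcie.outcome import association_trajectory
        naive = association_trajectory(fit, info, grid)
        total = trajectory_with_bootstrap_ci(fit, info, grid, boot)
        assert np.mean(total.level_var) > 0.8 * np.mean(naive.level_var)
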