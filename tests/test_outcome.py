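"""Stage-2 outcome model, AIC selection, delta-method trajectories."""

import numpy as np
import pandas as pd
import pytest

from wcie.bases import BasisSpec, NATURAL_CUBIC, make_basis
from wcie.history import HistoryCovariates, history_covariates
from wcie.lmm import fit_lmm_arrays
from wcie.outcome import (
    association_trajectory,
    build_outcome_design,
    fit_outcome_model,
    select_weight_basis,
)

WEIGHT = BasisSpec(NATURAL_CUBIC, (-16.0, -8.0), (-24.0, 0.0), include_intercept=True)


@pytest.fixture(scope="module")
def H(predicted):
    return history_covariates(predicted, WEIGHT)


@pytest.fixture(scope="module")
def stage2(small_cohort, H):
    _, outcome, _ = small_cohort
    return fit_outcome_model(outcome, H, confounders=("age0", "education"),
                             include_v0=True)


class TestDesign:
    def test_design_layout(self, small_cohort, H, stage2):
        fit, info = stage2
        names = info.fixed_names
        assert names[0] == "intercept"
        assert [names[i] for i in info.theta_level_idx] == ["H0", "H1", "H2", "H3"]
        assert [names[i] for i in info.theta_slope_idx] == [
            "H0:time", "H1:time", "H2:time", "H3:time"]
        assert "V0" in names

    def test_orphan_subjects_raise(self, small_cohort, H):
        _, outcome, _ = small_cohort
        extra = outcome.iloc[[0]].assign(id=99999)
        with pytest.raises(KeyError, match="lack exposure histories"):
            build_outcome_design(pd.concat([outcome, extra]), H)

    def test_negative_outcome_times_raise(self, small_cohort, H):
        _, outcome, _ = small_cohort
        bad = outcome.copy()
        bad.loc[bad.index[0], "time"] = -1.0
        with pytest.raises(ValueError, match=">= 0"):
            build_outcome_design(bad, H)


class TestTrajectory:
    def test_point_estimates_recover_scenario_a(self, stage2):
        fit, info = stage2
        traj = association_trajectory(fit, info, np.arange(-24.0, 0.5, 1.0))
        # truth: constant -0.05 (level) and -0.01 (slope); n=150, so loose
        assert traj.overall_mean_level == pytest.approx(-0.05, abs=0.02)
        assert traj.overall_mean_slope == pytest.approx(-0.01, abs=0.008)

    def test_delta_method_matches_monte_carlo(self, stage2):
        # pointwise delta-method variance vs push-forward of 20k theta draws
        fit, info = stage2
        grid = np.arange(-24.0, 0.5, 1.0)
        traj = association_trajectory(fit, info, grid)
        rng = np.random.default_rng(123)
        V = fit.fixed_vcov[np.ix_(info.theta_level_idx, info.theta_level_idx)]
        draws = rng.multivariate_normal(
            fit.fixed_estimates[info.theta_level_idx], V, size=20000)
        B = make_basis(info.weight_basis, grid).values
        mc_sd = (draws @ B.T).std(axis=0, ddof=1)
        np.testing.assert_allclose(traj.level_se, mc_sd, rtol=0.02)

    def test_reparameterization_invariance(self, small_cohort, predicted):
        # an invertible mix of the H columns must leave the trajectory alone.
        # Use the 3-column (one-knot) basis: with more columns the BLUP
        # histories make theta numerically ill-determined (design condition
        # ~2e5, squared again in the GLS normal equations) and no
        # parameterization can pin the trajectory to 1e-5
        _, outcome, _ = small_cohort
        basis = BasisSpec(NATURAL_CUBIC, (-12.0,), (-24.0, 0.0),
                          include_intercept=True)
        H = history_covariates(predicted, basis)
        # well-conditioned mix: orthogonal rotation times a mild rescaling,
        # so it tests the parameterization and not the conditioning of H
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        A = Q @ np.diag([0.5, 1.0, 2.0])
        H2 = HistoryCovariates(subject_ids=H.subject_ids, values=H.values @ A,
                               weight_basis=H.weight_basis, grid=H.grid)
        fit1, info1 = fit_outcome_model(outcome, H, ("age0", "education"), True)
        # invariance is exact at a common variance-parameter point, so hold
        # the variance parameters at the first fit's optimum; re-optimizing
        # would only add optimizer termination noise to the comparison
        fit2, info2 = fit_outcome_model(outcome, H2, ("age0", "education"), True,
                                        start_gamma=fit1.gamma, max_iter=0)
        grid = np.arange(-24.0, 0.5, 1.0)
        B = make_basis(basis, grid).values
        lvl1 = B @ fit1.fixed_estimates[info1.theta_level_idx]
        lvl2 = (B @ A) @ fit2.fixed_estimates[info2.theta_level_idx]
        np.testing.assert_allclose(lvl1, lvl2, atol=1e-5)
        slp1 = B @ fit1.fixed_estimates[info1.theta_slope_idx]
        slp2 = (B @ A) @ fit2.fixed_estimates[info2.theta_slope_idx]
        np.testing.assert_allclose(slp1, slp2, atol=1e-5)

    def test_no_vcov_warns_and_returns_point_only(self, small_cohort, H):
        _, outcome, _ = small_cohort
        fit, info = fit_outcome_model(outcome, H, ("age0", "education"), True)
        fit.fixed_vcov = None
        with pytest.warns(UserWarning, match="no covariance"):
            traj = association_trajectory(fit, info, np.arange(-24.0, 0.5, 1.0))
        assert traj.level_var is None

    def test_frame_schema(self, stage2):
        fit, info = stage2
        traj = association_trajectory(fit, info, np.arange(-24.0, 0.5, 1.0))
        frame = traj.to_frame()
        assert list(frame.columns) == [
            "t_U", "estimate_level", "se_level", "lo_level", "hi_level",
            "estimate_slope", "se_slope", "lo_slope", "hi_slope"]
        assert np.all(frame["lo_level"] <= frame["hi_level"])


class TestSelection:
    def test_winner_minimizes_aic(self, small_cohort, predicted):
        _, outcome, _ = small_cohort
        cands = [BasisSpec(NATURAL_CUBIC,
                           tuple(-24 + 24 * np.arange(1, k + 1) / (k + 1)),
                           (-24.0, 0.0), include_intercept=True)
                 for k in (1, 2, 3)]
        spec, fit, info, H, table = select_weight_basis(
            outcome, predicted, cands, confounders=("age0", "education"),
            include_v0=True)
        assert fit.aic == pytest.approx(table["aic"].min())
        assert len(table) == 3

    def test_tie_breaks_to_fewer_columns(self, small_cohort, predicted):
        # listing the same basis twice yields an exact AIC tie; the smaller
        # column count (equal here) resolves to the first entry stably
        _, outcome, _ = small_cohort
        b = BasisSpec(NATURAL_CUBIC, (-12.0,), (-24.0, 0.0), include_intercept=True)
        spec, *_ , table = select_weight_basis(
            outcome, predicted, [b, b], confounders=("age0", "education"))
        assert spec == b and len(table) == 2

    def test_empty_candidates(self, small_cohort, predicted):
        _, outcome, _ = small_cohort
        with pytest.raises(ValueError, match="empty"):
            select_weight_basis(outcome, predicted, [])
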