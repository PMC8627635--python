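"""Parametric bootstrap propagating stage-1 uncertainty into stage 2.

The H summaries entering the outcome model are built from *predicted*
exposure histories, so the naive stage-2 covariance ignores the sampling
error of the stage-1 parameters.  The parametric bootstrap draws stage-1
parameters from their asymptotic Gaussian, recomputes the BLUPs, the
predicted histories and the H summaries under each draw, refits the
outcome model, and combines the within-draw and between-draw variability
into the total covariance

    V_tot = (1/M) sum_m V_intra_m
          + (1/M) sum_m (phi_m - phi_bar)(phi_m - phi_bar)'

over the stage-2 fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wcie.bases import BasisSpec
from wcie.exposure import ExposureHistoryModel
from wcie.history import history_covariates
from wcie.lmm import LmmFit, sample_parameters
from wcie.outcome import (
    AssociationTrajectory,
    OutcomeDesignInfo,
    association_trajectory,
    fit_outcome_model,
)

__all__ = ["BootstrapResult", "bootstrap_total_variance", "trajectory_with_bootstrap_ci"]


@dataclass
class BootstrapResult:
    """Total covariance of the stage-2 fixed effects under Eq. (12)."""

    V_tot: np.ndarray
    V_intra: np.ndarray          # mean of the within-draw covariances
    V_between: np.ndarray        # scatter of the refitted fixed effects
    phi_draws: np.ndarray        # (M_eff, p) stage-2 fixed effects per draw
    n_requested: int
    n_failed: int
    denominator: str = "M"

    @property
    def n_effective(self) -> int:
        return self.phi_draws.shape[0]


def bootstrap_total_variance(
    exposure_model: ExposureHistoryModel,
    outcome_panel,
    weight_basis: BasisSpec,
    point_fit: LmmFit,
    n_draws: int = 500,
    seed=None,
    confounders=(),
    include_v0: bool = False,
    history_mode: str = "discrete-sum",
    denominator: str = "M",
    param_set: str = "all",
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Run the parametric bootstrap and assemble the total covariance.

    Each draw replaces the stage-1 parameters (fixed effects, residual SD,
    random-effect covariance) by a sample from their joint asymptotic
    Gaussian; BLUPs and H are recomputed and the stage-2 model is refitted,
    warm-started at the point estimate's variance parameters.  Draws whose
    refit raises or fails to converge are dropped; more than
    ``max_failure_fraction`` failures aborts with an error because the
    remaining draws would not be a fair sample.

    ``denominator="M"`` uses 1/M in both terms (the form above);
    ``"M-1"`` switches the between-draw term to the unbiased 1/(M-1).

    ``param_set`` chooses which stage-1 parameters are perturbed:
    ``"all"`` draws the full phi_U (fixed effects, residual SD and
    random-effect covariance); ``"fixed"`` draws only the fixed effects
    and keeps the variance parameters at their estimates.  The source
    publication does not state which set enters V(phi_U); drawing the
    variance parameters too can destabilize the total variance when the
    random-effect covariance is weakly identified (many covariance
    parameters relative to the number of subjects), because large swings
    in the drawn covariance act nonlinearly on the BLUP predictions.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if denominator not in ("M", "M-1"):
        raise ValueError('denominator must be "M" or "M-1"')
    if param_set not in ("all", "fixed"):
        raise ValueError('param_set must be "all" or "fixed"')
    stage1: LmmFit = exposure_model.lmm_
    if stage1.vc_vcov is None:
        raise ValueError(
            "stage-1 fit lacks the variance-parameter covariance; "
            "refit the exposure model with compute_vcov=True"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = sample_parameters(stage1, n_draws, seed=rng)

    phi_list: list[np.ndarray] = []
    V_list: list[np.ndarray] = []
    n_failed = 0
    for m in range(n_draws):
        gamma_m = draws.gamma[m] if param_set == "all" else stage1.gamma
        try:
            pred = exposure_model.predict_history(
                beta=draws.beta[m], gamma_internal=gamma_m,
                provenance=f"bootstrap-draw-{m}",
            )
            H = history_covariates(pred, weight_basis, mode=history_mode)
            refit, _ = fit_outcome_model(
                outcome_panel, H, confounders, include_v0,
                compute_vc_vcov=False, start_gamma=point_fit.gamma,
            )
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        phi_list.append(refit.fixed_estimates)
        V_list.append(refit.fixed_vcov)

    if n_failed > max_failure_fraction * n_draws:
        raise RuntimeError(
            f"{n_failed}/{n_draws} bootstrap refits failed "
            f"(limit {max_failure_fraction:.0%}); the surviving draws are not "
            "a fair sample of the stage-1 parameter distribution"
        )
    phi = np.asarray(phi_list)
    M_eff = phi.shape[0]
    V_intra = np.mean(V_list, axis=0)
    centred = phi - phi.mean(axis=0)
    denom = M_eff if denominator == "M" else max(M_eff - 1, 1)
    V_between = centred.T @ centred / denom
    return BootstrapResult(
        V_tot=V_intra + V_between,
        V_intra=V_intra,
        V_between=V_between,
        phi_draws=phi,
        n_requested=n_draws,
        n_failed=n_failed,
        denominator=denominator,
    )


def trajectory_with_bootstrap_ci(
    point_fit: LmmFit,
    info: OutcomeDesignInfo,
    grid: np.ndarray,
    boot: BootstrapResult,
    ci_level: float = 0.95,
) -> AssociationTrajectory:
    """Association trajectories with CIs from the bootstrap total variance.

    Point estimates come from the original stage-2 fit; only the
    covariance is replaced by ``boot.V_tot``.
    """
    if boot.V_tot.shape[0] != point_fit.fixed_estimates.size:
        raise ValueError("bootstrap covariance does not match the stage-2 fixed effects")
    return association_trajectory(
        point_fit, info, grid, vcov=boot.V_tot,
        ci_level=ci_level, variance_source="bootstrap",
    )
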