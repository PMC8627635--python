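"""Landmark weighted-cumulative-exposure estimator: the full two-stage pipeline.

``LandmarkWCIE`` chains the stages end to end: reconstruct individual
exposure histories on [-window, 0] with a mixed model (stage 1), collapse
them into weighted-cumulative-index summaries for each candidate weight
basis, pick the basis by AIC in the outcome mixed model (stage 2), and
propagate stage-1 uncertainty into the association-trajectory confidence
bands with a parametric bootstrap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from wcie.bases import NATURAL_CUBIC, BasisSpec
from wcie.bootstrap import bootstrap_total_variance, trajectory_with_bootstrap_ci
from wcie.exposure import ExposureHistoryModel
from wcie.outcome import association_trajectory, select_weight_basis

__all__ = ["LandmarkWCIE", "default_weight_candidates"]


def default_weight_candidates(
    window: float, knot_counts: Sequence[int] = (1, 2, 3, 4, 5)
) -> list[BasisSpec]:
    """Natural cubic weight bases with equidistant inner knots on [-window, 0]."""
    out = []
    for n in knot_counts:
        knots = -window + window * np.arange(1, n + 1) / (n + 1)
        out.append(BasisSpec(NATURAL_CUBIC, tuple(knots), (-window, 0.0),
                             include_intercept=True))
    return out


class LandmarkWCIE(BaseEstimator):
    """Time-varying association between an exposure history and an outcome.

    Parameters
    ----------
    window:
        Length S of the retrospective exposure window in years; the
        landmark is time 0.
    grid_step:
        Spacing of the prediction grid for the reconstructed histories.
    exposure_n_inner_knots, exposure_knot_mode, exposure_random_structure:
        Stage-1 trajectory model settings (see
        :class:`~wcie.exposure.ExposureHistoryModel`).
    confounders:
        Baseline covariate columns, required in both panels; they enter
        the stage-1 fixed effects and both the level and slope parts of
        stage 2.
    include_v0:
        Add a first-visit indicator to the stage-2 level submodel (a
        simple first-passing / retest-effect adjustment).
    weight_knot_candidates:
        Inner-knot counts of the candidate weight bases compared by AIC.
    history_mode:
        ``"discrete-sum"`` (yearly sum) or ``"quadrature"`` (trapezoidal
        integral) definition of the cumulative index.
    n_bootstrap:
        Parametric-bootstrap draws for the total variance; 0 skips the
        bootstrap and the trajectory keeps the naive stage-2 covariance.
    bootstrap_param_set:
        ``"all"`` perturbs every stage-1 parameter in the bootstrap;
        ``"fixed"`` perturbs the fixed effects only (see
        :func:`~wcie.bootstrap.bootstrap_total_variance`).
    ci_level, random_state:
        Confidence level of the bands and the bootstrap seed.
    """

    def __init__(
        self,
        window: float = 24.0,
        grid_step: float = 1.0,
        exposure_n_inner_knots: int = 4,
        exposure_knot_mode: str = "quantile",
        exposure_random_structure: str = "spline",
        confounders: Sequence[str] = ("age0", "education"),
        include_v0: bool = False,
        weight_knot_candidates: Sequence[int] = (1, 2, 3, 4, 5),
        history_mode: str = "discrete-sum",
        n_bootstrap: int = 500,
        bootstrap_param_set: str = "all",
        ci_level: float = 0.95,
        random_state=None,
        max_iter: int = 500,
    ):
        self.window = window
        self.grid_step = grid_step
        self.exposure_n_inner_knots = exposure_n_inner_knots
        self.exposure_knot_mode = exposure_knot_mode
        self.exposure_random_structure = exposure_random_structure
        self.confounders = confounders
        self.include_v0 = include_v0
        self.weight_knot_candidates = weight_knot_candidates
        self.history_mode = history_mode
        self.n_bootstrap = n_bootstrap
        self.bootstrap_param_set = bootstrap_param_set
        self.ci_level = ci_level
        self.random_state = random_state
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def fit(self, exposure_panel: pd.DataFrame, outcome_panel: pd.DataFrame) -> "LandmarkWCIE":
        self.exposure_model_ = ExposureHistoryModel(
            window=self.window,
            grid_step=self.grid_step,
            n_inner_knots=self.exposure_n_inner_knots,
            knot_mode=self.exposure_knot_mode,
            covariates=tuple(self.confounders),
            random_structure=self.exposure_random_structure,
            compute_vcov=self.n_bootstrap > 0,
            max_iter=self.max_iter,
        ).fit(exposure_panel)
        self.predicted_exposure_ = self.exposure_model_.predict_history()

        candidates = default_weight_candidates(self.window, self.weight_knot_candidates)
        (self.weight_basis_, self.outcome_fit_, self.outcome_info_,
         self.history_, self.aic_table_) = select_weight_basis(
            outcome_panel, self.predicted_exposure_, candidates,
            confounders=tuple(self.confounders), include_v0=self.include_v0,
            history_mode=self.history_mode, max_iter=self.max_iter,
        )

        grid = self.exposure_model_.grid_
        if self.n_bootstrap > 0:
            self.bootstrap_ = bootstrap_total_variance(
                self.exposure_model_, outcome_panel, self.weight_basis_,
                self.outcome_fit_, n_draws=self.n_bootstrap,
                seed=self.random_state, confounders=tuple(self.confounders),
                include_v0=self.include_v0, history_mode=self.history_mode,
                param_set=self.bootstrap_param_set,
            )
            self.trajectory_ = trajectory_with_bootstrap_ci(
                self.outcome_fit_, self.outcome_info_, grid,
                self.bootstrap_, ci_level=self.ci_level,
            )
        else:
            self.bootstrap_ = None
            self.trajectory_ = association_trajectory(
                self.outcome_fit_, self.outcome_info_, grid,
                ci_level=self.ci_level, variance_source="naive",
            )
        return self

    # ------------------------------------------------------------------
    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy frame of the association trajectories with CIs."""
        self._check_fitted()
        return self.trajectory_.to_frame()

    @property
    def overall_mean_level_(self) -> float:
        self._check_fitted()
        return self.trajectory_.overall_mean_level

    @property
    def overall_mean_slope_(self) -> float:
        self._check_fitted()
        return self.trajectory_.overall_mean_slope

    def _check_fitted(self) -> None:
        if not hasattr(self, "trajectory_"):
            raise AttributeError("this LandmarkWCIE instance is not fitted yet")
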