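"""Stage 1: mixed model for the pre-landmark exposure trajectory.

The exposure (e.g. BMI) is observed intermittently and with error on the
retrospective window [-S, 0].  A linear mixed model with a natural cubic
spline of time in both the fixed and the random part reconstructs each
subject's error-free trajectory; the fitted fixed effects plus the
subject's BLUP then predict the exposure on a regular grid covering the
whole window, including times where the subject was never observed —
which is how intermittent missing visits are handled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from wcie.bases import NATURAL_CUBIC, BasisSpec, knot_placement, make_basis
from wcie.lmm import LmmFit, fit_lmm_arrays

__all__ = ["PredictedExposure", "ExposureHistoryModel", "fit_exposure_model", "predict_exposure_grid"]

_RANDOM_STRUCTURES = ("intercept", "slope", "spline")


@dataclass
class PredictedExposure:
    """Predicted error-free exposure for every subject on a common grid."""

    grid: np.ndarray           # t_U = -S, -S+step, ..., 0
    subject_ids: np.ndarray    # (N,)
    values: np.ndarray         # (N, len(grid))
    provenance: str = "estimate"

    def __post_init__(self) -> None:
        if self.values.shape != (self.subject_ids.size, self.grid.size):
            raise ValueError("values must be (n_subjects, n_grid)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite predicted exposures")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="id"),
                            columns=[f"t{g:g}" for g in self.grid])


class ExposureHistoryModel(BaseEstimator):
    """Mixed-model reconstruction of individual exposure histories.

    Parameters
    ----------
    window:
        Length S of the retrospective window; exposure times must lie in
        [-window, 0] (the landmark is time 0).
    grid_step:
        Spacing of the prediction grid, in years.  The default of 1 gives
        the S+1 yearly values that enter the cumulative index.
    n_inner_knots, knot_mode:
        Inner-knot count and placement (``"quantile"`` of the observed
        measurement times, or ``"equidistant"``) for the natural cubic
        spline describing the trajectory.
    inner_knots:
        Explicit inner knots overriding automatic placement.
    covariates:
        Baseline covariate columns entering the fixed effects.
    random_structure:
        ``"spline"`` (random intercept + all spline coefficients, the
        default), ``"slope"`` (random intercept + linear slope) or
        ``"intercept"``.  The reduced structures are for near-singular
        random-effect covariances or cheap exploratory fits.
    compute_vcov:
        Whether to compute the variance-parameter covariance needed by the
        parametric bootstrap.
    """

    def __init__(
        self,
        window: float = 24.0,
        grid_step: float = 1.0,
        n_inner_knots: int = 4,
        knot_mode: str = "quantile",
        inner_knots: Sequence[float] | None = None,
        covariates: Sequence[str] = ("age0", "education"),
        random_structure: str = "spline",
        compute_vcov: bool = True,
        max_iter: int = 500,
    ):
        self.window = window
        self.grid_step = grid_step
        self.n_inner_knots = n_inner_knots
        self.knot_mode = knot_mode
        self.inner_knots = inner_knots
        self.covariates = covariates
        self.random_structure = random_structure
        self.compute_vcov = compute_vcov
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def _validate_panel(self, panel: pd.DataFrame) -> pd.DataFrame:
        required = ["id", "time", "value", *self.covariates]
        missing = [c for c in required if c not in panel.columns]
        if missing:
            raise KeyError(f"exposure panel is missing columns {missing}")
        t = panel["time"].to_numpy(float)
        if np.any(t < -self.window - 1e-9) or np.any(t > 1e-9):
            raise ValueError(
                f"exposure times must lie in [-{self.window:g}, 0]; "
                f"found range [{t.min():g}, {t.max():g}]"
            )
        if self.random_structure not in _RANDOM_STRUCTURES:
            raise ValueError(f"random_structure must be one of {_RANDOM_STRUCTURES}")
        return panel.dropna(subset=["value"])

    def _designs(self, times: np.ndarray, covs: np.ndarray):
        F = make_basis(self.basis_, times).values
        X = np.column_stack([np.ones(times.size), covs, F])
        names = ["intercept", *self.covariates,
                 *[f"time_ns{k+1}" for k in range(F.shape[1])]]
        if self.random_structure == "intercept":
            Z = np.ones((times.size, 1))
        elif self.random_structure == "slope":
            Z = np.column_stack([np.ones(times.size), times])
        else:
            Z = np.column_stack([np.ones(times.size), F])
        return X, names, Z

    def fit(self, panel: pd.DataFrame, y=None) -> "ExposureHistoryModel":
        panel = self._validate_panel(panel)
        times = panel["time"].to_numpy(float)
        if self.inner_knots is not None:
            knots = np.asarray(self.inner_knots, dtype=float)
        else:
            knots = knot_placement(times, self.n_inner_knots, self.knot_mode,
                                   boundary=(-self.window, 0.0))
        self.basis_ = BasisSpec(NATURAL_CUBIC, tuple(knots), (-self.window, 0.0))
        covs = panel[list(self.covariates)].to_numpy(float)
        X, names, Z = self._designs(times, covs)
        self.lmm_ = fit_lmm_arrays(
            panel["value"].to_numpy(float), X, Z, panel["id"].to_numpy(),
            fixed_names=names, compute_vc_vcov=self.compute_vcov, max_iter=self.max_iter,
        )
        # baseline covariates per subject, aligned with the fit's group order
        per_subject = panel.groupby("id")[list(self.covariates)].first()
        self.subject_covariates_ = per_subject.reindex(self.lmm_.group_ids).to_numpy(float)
        self.grid_ = np.arange(-self.window, self.grid_step / 2.0, self.grid_step)
        n_spline = self.basis_.n_columns
        self._spline_slice = slice(1 + len(self.covariates), 1 + len(self.covariates) + n_spline)
        return self

    # ------------------------------------------------------------------
    def predict_history(
        self,
        beta: np.ndarray | None = None,
        gamma_internal: np.ndarray | None = None,
        provenance: str = "estimate",
    ) -> PredictedExposure:
        """Predicted exposure U*(t_U) for every subject on the grid.

        With no arguments, uses the ML estimates and the fitted BLUPs.
        ``beta``/``gamma_internal`` substitute a parameter draw (e.g. one
        bootstrap replicate), under which the BLUPs are recomputed.
        """
        fit: LmmFit = self.lmm_
        if beta is None:
            beta = fit.fixed_estimates
            blups = fit.blups
        else:
            if gamma_internal is None:
                raise ValueError("gamma_internal is required alongside beta")
            blups = fit.blups_at(beta, gamma_internal)
        Fg = make_basis(self.basis_, self.grid_).values
        ncov = len(self.covariates)
        fixed_subject = beta[0] + self.subject_covariates_ @ beta[1:1 + ncov]   # (N,)
        fixed_time = Fg @ beta[self._spline_slice]                              # (G,)
        if self.random_structure == "intercept":
            Zg = np.ones((self.grid_.size, 1))
        elif self.random_structure == "slope":
            Zg = np.column_stack([np.ones(self.grid_.size), self.grid_])
        else:
            Zg = np.column_stack([np.ones(self.grid_.size), Fg])
        values = fixed_subject[:, None] + fixed_time[None, :] + blups @ Zg.T
        return PredictedExposure(grid=self.grid_, subject_ids=fit.group_ids,
                                 values=values, provenance=provenance)


def fit_exposure_model(
    panel: pd.DataFrame,
    trajectory_basis: BasisSpec | None = None,
    covariates: Sequence[str] = ("age0", "education"),
    **kwargs,
) -> ExposureHistoryModel:
    """Functional wrapper around :class:`ExposureHistoryModel`.

    ``trajectory_basis`` may fix the spline explicitly; otherwise knots are
    placed from the observed times.  Returns the fitted model (its ``lmm_``
    attribute is the stage-1 :class:`~wcie.lmm.LmmFit`).
    """
    if trajectory_basis is not None:
        kwargs.setdefault("window", -trajectory_basis.boundary[0])
        kwargs["inner_knots"] = trajectory_basis.inner_knots
    model = ExposureHistoryModel(covariates=covariates, **kwargs)
    return model.fit(panel)


def predict_exposure_grid(model: ExposureHistoryModel, S: float | None = None,
                          step: float | None = None) -> PredictedExposure:
    """Predict each subject's exposure on the yearly grid over [-S, 0]."""
    if S is not None and abs(S - model.window) > 1e-9:
        raise ValueError("prediction window must match the fitted window")
    if step is not None and abs(step - model.grid_step) > 1e-9:
        raise ValueError("refit with the desired grid_step to change the grid")
    return model.predict_history()
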