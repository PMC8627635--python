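"""Stage 2: outcome mixed model with time-varying exposure-history effects.

The longitudinal outcome after the landmark is modelled with a linear
time trajectory; the exposure history acts on the level at the landmark
through the H summaries (coefficients theta_I) and on the annual slope
through H x time interactions (coefficients theta_S).  With the loading
coefficients fixed to 1 the weight functions ARE the time-varying
association trajectories,

    gamma*_I(t_U) = sum_k theta_Ik B_k(t_U),
    gamma*_S(t_U) = sum_k theta_Sk B_k(t_U),

and because these maps are linear in theta the delta-method pointwise
variance b(t_U)' V_theta b(t_U) is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from wcie.bases import NATURAL_CUBIC, BasisSpec, make_basis
from wcie.exposure import PredictedExposure
from wcie.history import HistoryCovariates, history_covariates
from wcie.lmm import LmmFit, fit_lmm_arrays

__all__ = [
    "OutcomeDesignInfo",
    "AssociationTrajectory",
    "fit_outcome_model",
    "select_weight_basis",
    "association_trajectory",
]


@dataclass
class OutcomeDesignInfo:
    """Bookkeeping for the stage-2 design: where the theta blocks live."""

    fixed_names: list[str]
    theta_level_idx: np.ndarray
    theta_slope_idx: np.ndarray
    weight_basis: BasisSpec
    confounders: tuple[str, ...]
    include_v0: bool
    history_mode: str = "discrete-sum"


@dataclass
class AssociationTrajectory:
    """Time-varying association of exposure history with level and slope.

    ``overall_mean_*`` is the average of the trajectory over the S+1 grid
    points: the overall mean effect of one unit of exposure history.
    """

    grid: np.ndarray
    level_effect: np.ndarray
    slope_effect: np.ndarray
    level_var: np.ndarray | None = None
    slope_var: np.ndarray | None = None
    ci_level: float = 0.95
    variance_source: str = "none"
    weight_basis: BasisSpec | None = field(default=None, repr=False)

    @property
    def level_se(self) -> np.ndarray | None:
        return None if self.level_var is None else np.sqrt(self.level_var)

    @property
    def slope_se(self) -> np.ndarray | None:
        return None if self.slope_var is None else np.sqrt(self.slope_var)

    def _bounds(self, effect, var):
        z = sps.norm.ppf(0.5 + self.ci_level / 2.0)
        se = np.sqrt(var)
        return effect - z * se, effect + z * se

    @property
    def overall_mean_level(self) -> float:
        return float(self.level_effect.mean())

    @property
    def overall_mean_slope(self) -> float:
        return float(self.slope_effect.mean())

    def to_frame(self) -> pd.DataFrame:
        out = {"t_U": self.grid,
               "estimate_level": self.level_effect,
               "estimate_slope": self.slope_effect}
        if self.level_var is not None:
            lo, hi = self._bounds(self.level_effect, self.level_var)
            out.update(se_level=self.level_se, lo_level=lo, hi_level=hi)
        if self.slope_var is not None:
            lo, hi = self._bounds(self.slope_effect, self.slope_var)
            out.update(se_slope=self.slope_se, lo_slope=lo, hi_slope=hi)
        order = ["t_U", "estimate_level", "se_level", "lo_level", "hi_level",
                 "estimate_slope", "se_slope", "lo_slope", "hi_slope"]
        return pd.DataFrame(out)[[c for c in order if c in out]]


# ---------------------------------------------------------------------------


def build_outcome_design(
    panel: pd.DataFrame,
    H: HistoryCovariates,
    confounders: Sequence[str] = (),
    include_v0: bool = False,
):
    """Assemble the stage-2 stacked design with H on level and slope."""
    required = ["id", "time", "value", *confounders]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise KeyError(f"outcome panel is missing columns {missing}")
    t = panel["time"].to_numpy(float)
    if np.any(t < -1e-9):
        raise ValueError("outcome times must be >= 0 (the landmark)")

    h_index = pd.Index(H.subject_ids)
    pos = h_index.get_indexer(panel["id"])
    if np.any(pos < 0):
        orphans = sorted(set(panel["id"][pos < 0]))
        raise KeyError(
            f"{len(orphans)} outcome subjects lack exposure histories, e.g. {orphans[:5]}"
        )
    Hrows = H.values[pos]                                   # (n_rows, K+1)
    nK = Hrows.shape[1]

    cols = [np.ones(t.size)]
    names = ["intercept"]
    for c in confounders:
        cols.append(panel[c].to_numpy(float))
        names.append(c)
    for k in range(nK):
        cols.append(Hrows[:, k])
        names.append(f"H{k}")
    if include_v0:
        if "V0" in panel.columns:
            v0 = panel["V0"].to_numpy(float)
        else:
            v0 = (panel["time"] == panel.groupby("id")["time"].transform("min")).to_numpy(float)
        cols.append(v0)
        names.append("V0")
    theta_level_idx = np.array([names.index(f"H{k}") for k in range(nK)])

    cols.append(t)
    names.append("time")
    for c in confounders:
        cols.append(panel[c].to_numpy(float) * t)
        names.append(f"{c}:time")
    base = len(names)
    for k in range(nK):
        cols.append(Hrows[:, k] * t)
        names.append(f"H{k}:time")
    theta_slope_idx = np.arange(base, base + nK)

    X = np.column_stack(cols)
    Z = np.column_stack([np.ones(t.size), t])
    info = OutcomeDesignInfo(
        fixed_names=names,
        theta_level_idx=theta_level_idx,
        theta_slope_idx=theta_slope_idx,
        weight_basis=H.weight_basis,
        confounders=tuple(confounders),
        include_v0=include_v0,
        history_mode=H.mode,
    )
    return panel["value"].to_numpy(float), X, Z, panel["id"].to_numpy(), info


def fit_outcome_model(
    panel: pd.DataFrame,
    H: HistoryCovariates,
    confounders: Sequence[str] = (),
    include_v0: bool = False,
    **lmm_kwargs,
) -> tuple[LmmFit, OutcomeDesignInfo]:
    """ML fit of the outcome model with correlated random intercept/slope."""
    y, X, Z, groups, info = build_outcome_design(panel, H, confounders, include_v0)
    fit = fit_lmm_arrays(y, X, Z, groups, fixed_names=info.fixed_names, **lmm_kwargs)
    return fit, info


def select_weight_basis(
    panel: pd.DataFrame,
    pred: PredictedExposure,
    candidates: Sequence[BasisSpec],
    confounders: Sequence[str] = (),
    include_v0: bool = False,
    history_mode: str = "discrete-sum",
    **lmm_kwargs,
):
    """Refit stage 2 for each candidate weight basis and keep the AIC winner.

    H is recomputed per basis.  Ties (within 1e-9) go to the basis with
    fewer columns.  Non-convergent candidates are excluded with a warning;
    if every candidate fails, an error is raised.

    Returns ``(best_spec, best_fit, best_info, best_H, aic_table)``.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    rows = []
    fits = []
    for spec in candidates:
        H = history_covariates(pred, spec, mode=history_mode)
        try:
            fit, info = fit_outcome_model(panel, H, confounders, include_v0, **lmm_kwargs)
        except np.linalg.LinAlgError as err:
            warnings.warn(f"candidate {spec.kind} with {len(spec.inner_knots)} inner knots "
                          f"failed: {err}", stacklevel=2)
            continue
        if not fit.converged:
            warnings.warn(f"candidate with {len(spec.inner_knots)} inner knots did not "
                          "converge; excluded from selection", stacklevel=2)
            continue
        rows.append({"kind": spec.kind, "n_inner_knots": len(spec.inner_knots),
                     "n_columns": spec.n_columns, "loglik": fit.loglik,
                     "n_params": fit.n_params, "aic": fit.aic})
        fits.append((spec, fit, info, H))
    if not fits:
        raise RuntimeError("no weight-basis candidate converged")
    table = pd.DataFrame(rows)
    aic = table["aic"].to_numpy()
    ncol = table["n_columns"].to_numpy()
    best = int(np.lexsort((ncol, np.round(aic / 1e-9) * 1e-9))[0])
    return (*fits[best], table)


def association_trajectory(
    fit: LmmFit,
    info: OutcomeDesignInfo,
    grid: np.ndarray,
    vcov: np.ndarray | None = None,
    ci_level: float = 0.95,
    variance_source: str = "naive",
) -> AssociationTrajectory:
    """Evaluate the level and slope association trajectories on a grid.

    ``vcov`` is the covariance of the stage-2 fixed effects (naive GLS by
    default, or a bootstrap total variance); the pointwise variance is the
    exact push-forward b(t_U)' V_theta b(t_U) of the theta blocks.
    """
    grid = np.asarray(grid, dtype=float)
    B = make_basis(info.weight_basis, grid).values
    beta = fit.fixed_estimates
    level = B @ beta[info.theta_level_idx]
    slope = B @ beta[info.theta_slope_idx]
    if vcov is None:
        vcov = fit.fixed_vcov
        if vcov is None:
            warnings.warn("no covariance available; trajectory returned without CIs",
                          stacklevel=2)
            return AssociationTrajectory(grid=grid, level_effect=level, slope_effect=slope,
                                         ci_level=ci_level, variance_source="none",
                                         weight_basis=info.weight_basis)
    V_I = vcov[np.ix_(info.theta_level_idx, info.theta_level_idx)]
    V_S = vcov[np.ix_(info.theta_slope_idx, info.theta_slope_idx)]
    level_var = np.einsum("gi,ij,gj->g", B, V_I, B)
    slope_var = np.einsum("gi,ij,gj->g", B, V_S, B)
    return AssociationTrajectory(
        grid=grid, level_effect=level, slope_effect=slope,
        level_var=level_var, slope_var=slope_var,
        ci_level=ci_level, variance_source=variance_source,
        weight_basis=info.weight_basis,
    )
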