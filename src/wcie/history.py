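"""Summary covariates of the exposure history.

Writing the weight function on a spline basis turns the weighted
cumulative index of exposure into a linear combination of a handful of
per-subject summaries

    H_ki = sum_{t_U = -S}^{0} B_k(t_U) * U*_i(t_U),    k = 0..K,

with B_0 = 1 so that H_0i is the plain (unweighted) cumulative index.
These H columns are ordinary regression covariates in the outcome model;
their coefficients are the weight-function coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wcie.bases import BasisSpec, make_basis
from wcie.exposure import PredictedExposure

__all__ = ["HistoryCovariates", "history_covariates", "wcie_value"]


@dataclass
class HistoryCovariates:
    """Per-subject summaries H_ki of the predicted exposure history."""

    subject_ids: np.ndarray
    values: np.ndarray          # (N, K+1) including the intercept column
    weight_basis: BasisSpec
    grid: np.ndarray
    mode: str = "discrete-sum"

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.weight_basis.n_columns:
            raise ValueError("H column count must match the weight basis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite history covariates")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"H{k}" for k in range(self.values.shape[1])]
        return pd.DataFrame(self.values, columns=cols,
                            index=pd.Index(self.subject_ids, name="id"))


def history_covariates(
    pred: PredictedExposure,
    weight_basis: BasisSpec,
    mode: str = "discrete-sum",
) -> HistoryCovariates:
    """Collapse predicted exposure histories into the H_ki summaries.

    ``mode="discrete-sum"`` is the yearly sum over the grid (the default
    definition of the index); ``mode="quadrature"`` replaces the sum with
    trapezoidal integration of B_k(t) U*(t) over the window, the
    continuous-time variant of the index.
    """
    lo, hi = weight_basis.boundary
    if abs(lo - pred.grid[0]) > 1e-9 or abs(hi - pred.grid[-1]) > 1e-9:
        raise ValueError(
            f"weight-basis window [{lo:g}, {hi:g}] does not match the "
            f"prediction grid [{pred.grid[0]:g}, {pred.grid[-1]:g}]"
        )
    B = make_basis(weight_basis, pred.grid).values          # (G, K+1)
    if mode == "discrete-sum":
        H = pred.values @ B
    elif mode == "quadrature":
        w = np.ones(pred.grid.size)
        w[0] = w[-1] = 0.5
        w *= np.diff(pred.grid).mean()
        H = (pred.values * w) @ B
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return HistoryCovariates(subject_ids=pred.subject_ids, values=H,
                             weight_basis=weight_basis, grid=pred.grid, mode=mode)


def wcie_value(H: HistoryCovariates, theta: np.ndarray) -> np.ndarray:
    """Per-subject weighted cumulative index, sum_k theta_k H_ki.

    With the identifiability convention (loading coefficient fixed to 1)
    this is exactly the covariate value implied by the weight coefficients.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != H.values.shape[1]:
        raise ValueError(
            f"theta has {theta.size} entries but H has {H.values.shape[1]} columns"
        )
    return H.values @ theta
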