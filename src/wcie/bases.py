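"""Spline and piecewise-constant bases over a retrospective time window.

Two uses share this module: flexible modelling of the individual exposure
trajectory in the first-stage mixed model, and the weight function w(t_U)
that turns the cumulative exposure index into a *weighted* one.  Both are
linear bases evaluated on a time grid, so downstream code treats them
identically.

The natural cubic spline follows the classic truncated-power construction
with natural (linearity) constraints beyond the boundary knots: with
``K + 1`` total knots the basis spans ``K`` columns (excluding the optional
intercept), is cubic between knots and exactly linear outside the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "make_basis",
    "knot_placement",
]

NATURAL_CUBIC = "natural-cubic-spline"
PIECEWISE = "piecewise-constant"


class InvalidBasisSpecError(ValueError):
    """Raised for unordered/duplicate knots or an inconsistent window."""


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a basis over a closed time window.

    Parameters
    ----------
    kind:
        ``"natural-cubic-spline"`` or ``"piecewise-constant"``.
    inner_knots:
        Strictly increasing knots (spline) or segment breaks (piecewise),
        all strictly inside ``boundary``.  May be empty: the spline then
        degenerates to a linear function of time and the piecewise basis
        to a constant weight over the whole window.
    boundary:
        The window ``[lo, hi]`` in time units (years).  For the natural
        cubic spline the boundary points act as boundary knots.
    include_intercept:
        Whether a leading column identically equal to 1 is part of the
        basis.  The weight function includes it (its coefficient is the
        constant part of w); the exposure-trajectory basis does not
        (the model intercept lives in the fixed effects).
    """

    kind: str
    inner_knots: tuple[float, ...]
    boundary: tuple[float, float]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "inner_knots", tuple(float(k) for k in self.inner_knots))
        object.__setattr__(self, "boundary", (float(self.boundary[0]), float(self.boundary[1])))
        if self.kind not in (NATURAL_CUBIC, PIECEWISE):
            raise InvalidBasisSpecError(f"unknown basis kind: {self.kind!r}")
        lo, hi = self.boundary
        if not lo < hi:
            raise InvalidBasisSpecError(f"window must satisfy lo < hi, got [{lo}, {hi}]")
        ks = np.asarray(self.inner_knots, dtype=float)
        if ks.size == 0:
            # no inner knots is a valid degenerate basis: linear over the
            # window for the spline, constant for the piecewise kind
            return
        if np.any(np.diff(ks) <= 0):
            raise InvalidBasisSpecError(f"inner knots must be strictly increasing: {self.inner_knots}")
        if ks[0] <= lo or ks[-1] >= hi:
            raise InvalidBasisSpecError(
                f"inner knots must lie strictly inside ({lo}, {hi}): {self.inner_knots}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        """Boundary and inner knots, in increasing order (spline only)."""
        lo, hi = self.boundary
        return np.asarray([lo, *self.inner_knots, hi], dtype=float)

    @property
    def n_columns(self) -> int:
        """Number of basis columns, including the intercept when present."""
        if self.kind == NATURAL_CUBIC:
            n = len(self.inner_knots) + 1  # K+1 total knots -> K columns
        else:
            # one indicator per segment; with an intercept the first
            # segment's indicator is dropped (same span, no collinearity)
            n = len(self.inner_knots) + 1 if not self.include_intercept else len(self.inner_knots)
        return n + (1 if self.include_intercept else 0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "inner_knots": list(self.inner_knots),
            "boundary": list(self.boundary),
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            kind=d["kind"],
            inner_knots=tuple(d["inner_knots"]),
            boundary=tuple(d["boundary"]),
            include_intercept=bool(d.get("include_intercept", False)),
        )


@dataclass(frozen=True)
class BasisMatrix:
    """A basis evaluated on a grid: rows = times, columns = functions."""

    times: np.ndarray
    values: np.ndarray
    spec: BasisSpec = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (self.times.size, self.spec.n_columns):
            raise ValueError(
                f"basis shape {self.values.shape} inconsistent with "
                f"{self.times.size} times x {self.spec.n_columns} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("basis contains non-finite entries")


def _natural_cubic_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline columns (no intercept).

    With knots xi_1 < ... < xi_Q the columns are N_1(x) = x and, for
    k = 1..Q-2, N_{k+1}(x) = [d_k(x) - d_{Q-1}(x)] / (xi_Q - xi_1)^2 where
    d_k(x) = [(x - xi_k)^3_+ - (x - xi_Q)^3_+] / (xi_Q - xi_k).
    Second and third derivatives vanish at and beyond the boundary knots.
    The curvature columns carry a fixed 1/(window span)^2 normalization so
    that all columns share the scale of x, which keeps downstream design
    matrices well conditioned without changing the spanned space.
    """
    q = knots.size
    xi_q = knots[-1]
    pos_last = np.clip(x - xi_q, 0.0, None) ** 3
    span2 = (knots[-1] - knots[0]) ** 2

    def d(k: int) -> np.ndarray:
        return (np.clip(x - knots[k], 0.0, None) ** 3 - pos_last) / (xi_q - knots[k])

    d_last = d(q - 2)
    cols = [x] + [(d(k) - d_last) / span2 for k in range(q - 2)]
    return np.column_stack(cols)


def _piecewise_columns(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    lo, hi = spec.boundary
    edges = np.asarray([lo, *spec.inner_knots, hi], dtype=float)
    # segment s covers [edges[s], edges[s+1]); the last segment is closed
    idx = np.searchsorted(edges, x, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    n_seg = edges.size - 1
    cols = np.zeros((x.size, n_seg))
    cols[np.arange(x.size), idx] = 1.0
    if spec.include_intercept:
        cols = cols[:, 1:]  # treatment coding against the first segment
    return cols


def make_basis(spec: BasisSpec, times: Sequence[float]) -> BasisMatrix:
    """Evaluate a basis specification on a grid of times.

    Times are expected inside the window; evaluation outside is permitted
    for the natural cubic spline (where the basis extrapolates linearly)
    but not for the piecewise-constant basis.
    """
    x = np.asarray(times, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty evaluation grid")
    if spec.kind == NATURAL_CUBIC:
        cols = _natural_cubic_columns(x, spec.all_knots)
    else:
        lo, hi = spec.boundary
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError("piecewise-constant basis cannot be evaluated outside its window")
        cols = _piecewise_columns(x, spec)
    if spec.include_intercept:
        cols = np.column_stack([np.ones(x.size), cols])
    return BasisMatrix(times=x, values=cols, spec=spec)


def knot_placement(
    times_observed: Sequence[float],
    n_inner: int,
    mode: str = "equidistant",
    boundary: tuple[float, float] | None = None,
) -> np.ndarray:
    """Place interior knots from observed times.

    ``equidistant`` spaces knots evenly inside the window (the window is
    ``boundary`` if given, else the observed range).  ``quantile`` puts
    them at empirical percentiles 100*i/(n_inner+1), i = 1..n_inner, with
    linear interpolation between order statistics.
    """
    t = np.asarray(times_observed, dtype=float).ravel()
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    distinct = np.unique(t)
    if distinct.size <= n_inner:
        raise ValueError(
            f"cannot place {n_inner} inner knots with only {distinct.size} distinct times"
        )
    lo, hi = boundary if boundary is not None else (distinct[0], distinct[-1])
    if not lo < hi:
        raise ValueError("observed times span a degenerate interval")
    if mode == "equidistant":
        return lo + (hi - lo) * np.arange(1, n_inner + 1) / (n_inner + 1)
    if mode == "quantile":
        probs = 100.0 * np.arange(1, n_inner + 1) / (n_inner + 1)
        knots = np.percentile(t, probs)
        if np.any(np.diff(knots) <= 0):
            raise ValueError(f"quantile knots are degenerate: {knots}")
        return knots
    raise ValueError(f"unknown knot placement mode: {mode!r}")
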