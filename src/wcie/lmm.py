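"""Maximum-likelihood linear mixed models with BLUPs and parameter sampling.

The model for subject i with n_i stacked observations is

    y_i = X_i beta + Z_i b_i + eps_i,   b_i ~ N(0, B),  eps_i ~ N(0, sigma^2 I)

estimated by ML (not REML) so that log-likelihoods and AICs are comparable
across mean structures.  Internally the covariance is parameterized as
B = sigma^2 * Gamma Gamma' with Gamma a free lower-triangular "relative
Cholesky" factor; beta and sigma^2 are profiled out of the deviance, which
is minimized over Gamma with an analytic gradient.  Per-subject sufficient
statistics (Z'Z, Z'X, Z'y and the global cross-products) make one deviance
evaluation O(N q^2 p) regardless of the number of observations, which is
what keeps the parametric bootstrap affordable.

The reporting/sampling scale for the variance parameters is the raw
Cholesky scale (sigma, vech of the Cholesky factor L of B): any Gaussian
draw on it maps back to a valid parameter set, because L L' is PSD for
every L and sigma enters only through its absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LmmSpec",
    "LmmFit",
    "ParameterDraws",
    "fit_lmm",
    "fit_lmm_arrays",
    "blup",
    "sample_parameters",
]

_LOG2PI = np.log(2.0 * np.pi)


class RankDeficientError(np.linalg.LinAlgError):
    """Fixed-effect design is singular; the message names suspect columns."""


class UnknownSubjectError(KeyError):
    """Requested subject is not part of the fitted panel."""


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass
class _SuffStats:
    """Per-subject and global cross-products of a grouped linear model."""

    group_ids: np.ndarray          # (N,) original labels, fit order
    counts: np.ndarray             # (N,) observations per subject
    ZtZ: np.ndarray                # (N, q, q)
    ZtX: np.ndarray                # (N, q, p)
    Zty: np.ndarray                # (N, q)
    XtX: np.ndarray                # (p, p)
    Xty: np.ndarray                # (p,)
    yty: float
    n_obs: int

    @property
    def n_groups(self) -> int:
        return self.group_ids.size

    @property
    def q(self) -> int:
        return self.ZtZ.shape[1]

    @property
    def p(self) -> int:
        return self.ZtX.shape[2]


def _build_stats(y: np.ndarray, X: np.ndarray, Z: np.ndarray, groups: np.ndarray) -> _SuffStats:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    groups = np.asarray(groups)
    if not (y.size == X.shape[0] == Z.shape[0] == groups.size):
        raise ValueError("y, X, Z and groups must have matching first dimension")
    uniq, codes = np.unique(groups, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    Xs, Zs, ys, cs = X[order], Z[order], y[order], codes[order]
    counts = np.bincount(cs, minlength=uniq.size)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    ZtZ = np.add.reduceat(Zs[:, :, None] * Zs[:, None, :], starts, axis=0)
    ZtX = np.add.reduceat(Zs[:, :, None] * Xs[:, None, :], starts, axis=0)
    Zty = np.add.reduceat(Zs * ys[:, None], starts, axis=0)
    return _SuffStats(
        group_ids=uniq,
        counts=counts,
        ZtZ=ZtZ,
        ZtX=ZtX,
        Zty=Zty,
        XtX=Xs.T @ Xs,
        Xty=Xs.T @ ys,
        yty=float(ys @ ys),
        n_obs=y.size,
    )


# ---------------------------------------------------------------------------
# profiled deviance


def _gamma_from_vec(vec: np.ndarray, q: int) -> np.ndarray:
    G = np.zeros((q, q))
    G[np.tril_indices(q)] = vec
    return G


def _core_quantities(G: np.ndarray, stats: _SuffStats):
    """Shared pieces: A_i = I + Gamma' Z'Z Gamma and friends."""
    q = stats.q
    CG = stats.ZtZ @ G                                   # (N,q,q) = C Gamma
    W = np.einsum("ij,nik->njk", G, CG)                  # Gamma' C Gamma
    A = W + np.eye(q)
    cholA = np.linalg.cholesky(A)
    logdet = 2.0 * np.log(np.diagonal(cholA, axis1=1, axis2=2)).sum()
    U = np.einsum("ij,nip->njp", G, stats.ZtX)           # Gamma' Z'X
    u = np.einsum("ij,ni->nj", G, stats.Zty)             # Gamma' Z'y
    AinvU = np.linalg.solve(A, U)
    Ainvu = np.linalg.solve(A, u[:, :, None])[:, :, 0]
    M = stats.XtX - np.einsum("nij,nik->jk", U, AinvU)   # X' V0^-1 X
    v = stats.Xty - np.einsum("nij,ni->j", U, Ainvu)     # X' V0^-1 y
    yPy = stats.yty - np.einsum("ni,ni->", u, Ainvu)     # y' V0^-1 y
    return CG, A, logdet, M, v, yPy


def _solve_gls(M: np.ndarray, v: np.ndarray, names: Sequence[str] | None = None,
               strict: bool = True) -> np.ndarray:
    try:
        c = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        if not strict:
            # transient loss of positive definiteness at a trial covariance
            # point during optimization: a pseudo-inverse solution keeps the
            # deviance defined so the line search can retreat; genuine rank
            # deficiency is still diagnosed at the final solution
            keep = w > max(w.max(), 0.0) * 1e-12
            w_inv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
            return (V * w_inv) @ (V.T @ v)
        bad = w < max(w.max(), 1.0) * 1e-10
        suspects = []
        if names is not None:
            for k in np.where(bad)[0]:
                j = int(np.argmax(np.abs(V[:, k])))
                suspects.append(names[j])
        raise RankDeficientError(
            "fixed-effect design is rank deficient"
            + (f"; collinear columns include {sorted(set(suspects))}" if suspects else "")
        ) from None
    z = np.linalg.solve(c, v)
    return np.linalg.solve(c.T, z)


def _profiled_deviance(vec: np.ndarray, stats: _SuffStats, names=None,
                       strict: bool = True):
    """Deviance (up to constants) profiled over beta and sigma^2, + gradient."""
    q, n = stats.q, stats.n_obs
    il = np.tril_indices(q)
    G = _gamma_from_vec(vec, q)
    CG, A, logdet, M, v, yPy = _core_quantities(G, stats)
    beta = _solve_gls(M, v, names, strict=strict)
    r = max(yPy - beta @ v, 1e-300)
    dev = logdet + n * np.log(r)
    # gradient wrt the free entries of Gamma
    grad_logdet = 2.0 * np.linalg.solve(A, CG.transpose(0, 2, 1)).transpose(0, 2, 1).sum(axis=0)
    g = stats.Zty - np.einsum("nip,p->ni", stats.ZtX, beta)      # Z'(y - X beta)
    Gg = np.einsum("ij,ni->nj", G, g)
    h = np.linalg.solve(A, Gg[:, :, None])[:, :, 0]
    CGh = np.einsum("nij,nj->ni", CG, h)
    grad_r = -2.0 * (np.einsum("ni,nj->ij", g, h) - np.einsum("ni,nj->ij", CGh, h))
    grad = grad_logdet + (n / r) * grad_r
    return dev, grad[il], beta, r


# ---------------------------------------------------------------------------
# unconstrained variance-parameter scale


def _vc_pack(sigma: float, B: np.ndarray) -> np.ndarray:
    """(sigma, B) -> [sigma, vech(chol(B))], the raw Cholesky scale.

    The diagonal is kept on its natural (not logged) scale so that
    Gaussian sampling around the estimate stays symmetric: any draw of
    the Cholesky entries still maps to a PSD covariance LL', whereas a
    log-diagonal scale would inflate the back-transformed covariances
    (lognormal mean > median) and distort the parametric bootstrap.
    """
    q = B.shape[0]
    jitter = 1e-10 * max(np.trace(B) / q, 1.0)
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    w = np.clip(w, jitter, None)
    L = np.linalg.cholesky(V @ np.diag(w) @ V.T)
    return np.concatenate([[sigma], L[np.tril_indices(q)]])


def _vc_unpack(vc: np.ndarray, q: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Inverse of :func:`_vc_pack`; returns (sigma, B, L).

    A negative sigma draw is folded back by |sigma| (the likelihood
    depends on sigma^2 only); sign flips of Cholesky columns leave both
    B = LL' and the BLUP map invariant.
    """
    sigma = float(max(abs(vc[0]), 1e-12))
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = vc[1:]
    return sigma, L @ L.T, L


def _loglik_at(stats: _SuffStats, beta: np.ndarray, sigma: float, L: np.ndarray) -> float:
    """Marginal Gaussian log-likelihood at arbitrary (beta, sigma, B=LL')."""
    n, q = stats.n_obs, stats.q
    G = L / sigma
    CG = stats.ZtZ @ G
    W = np.einsum("ij,nik->njk", G, CG)
    A = W + np.eye(q)
    cholA = np.linalg.cholesky(A)
    logdet = 2.0 * np.log(np.diagonal(cholA, axis1=1, axis2=2)).sum()
    g = stats.Zty - np.einsum("nip,p->ni", stats.ZtX, beta)
    Gg = np.einsum("ij,ni->nj", G, g)
    h = np.linalg.solve(A, Gg[:, :, None])[:, :, 0]
    ete = stats.yty - 2.0 * beta @ stats.Xty + beta @ stats.XtX @ beta
    Q = ete - np.einsum("ni,ni->", Gg, h)
    return -0.5 * (logdet + Q / sigma**2 + n * np.log(sigma**2) + n * _LOG2PI)


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth log-likelihood."""
    d = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _calibrate_vc_vcov(
    stats: _SuffStats,
    beta: np.ndarray,
    vc: np.ndarray,
    vc_vcov: np.ndarray,
    target_drop: float = 0.5,
    tol_factor: float = 4.0,
) -> tuple[np.ndarray, int]:
    """Trim draw directions where the quadratic approximation fails.

    The inverse observed information is only a valid draw covariance where
    the log-likelihood is locally quadratic.  Near a boundary of the
    covariance-parameter space (e.g. an almost-singular random-effect
    covariance) the surface is quartic in the Cholesky coordinates: flat
    at the optimum, sharply curved one step away, so information-based
    SDs overshoot by orders of magnitude and Gaussian draws land far
    outside the likelihood-supported region.

    For each eigendirection of the proposed covariance, the log-likelihood
    drop at one SD is evaluated; where it exceeds the quadratic value of
    0.5 by more than ``tol_factor``, the scale is shrunk until the drop
    matches ``target_drop``.  Directions where the approximation holds are
    untouched, so the calibrated covariance equals the asymptotic one
    whenever the asymptotics are in force.  Returns the calibrated
    covariance and the number of trimmed directions.
    """
    q = stats.q
    ll0 = _loglik_at(stats, beta, *_vc_unpack(vc, q)[::2])

    def drop(step: np.ndarray) -> float:
        return ll0 - _loglik_at(stats, beta, *_vc_unpack(vc + step, q)[::2])

    w, Vec = np.linalg.eigh(vc_vcov)
    w = np.clip(w, 0.0, None)
    n_trimmed = 0
    for k in range(w.size):
        s = np.sqrt(w[k])
        if s == 0.0:
            continue
        u = Vec[:, k]
        d = max(drop(s * u), drop(-s * u))
        if not np.isfinite(d) or d > tol_factor * target_drop:
            n_trimmed += 1
            t = s
            for _ in range(8):
                # between quadratic (drop ~ t^2) and quartic (drop ~ t^4)
                t *= (target_drop / max(d, target_drop)) ** (1.0 / 3.0)
                d = max(drop(t * u), drop(-t * u))
                if np.isfinite(d) and d <= tol_factor * target_drop:
                    break
            w[k] = t * t
    return (Vec * w) @ Vec.T, n_trimmed


def _psd_clip(S: np.ndarray) -> np.ndarray:
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    if w.min() >= 0:
        return S
    return V @ np.diag(np.clip(w, 0.0, None)) @ V.T


# ---------------------------------------------------------------------------
# public containers


@dataclass
class LmmFit:
    """A fitted linear mixed model.

    ``param_vcov()`` returns the joint covariance of the full parameter
    vector on its estimation scale, ordered as (beta, sigma, vech of
    chol(B)); the fixed-effect block is the exact GLS covariance and the
    variance block comes from the inverse observed information (Gaussian
    information is asymptotically block-diagonal between mean and
    covariance parameters).
    """

    fixed_names: list[str]
    fixed_estimates: np.ndarray
    fixed_vcov: np.ndarray
    re_cov: np.ndarray
    resid_sd: float
    vc_unconstrained: np.ndarray
    vc_vcov: np.ndarray | None
    loglik: float
    n_params: int
    converged: bool
    n_obs: int
    n_subjects: int
    group_ids: np.ndarray = field(repr=False)
    blups: np.ndarray = field(repr=False)  # (N, q) in group_ids order
    gamma: np.ndarray = field(repr=False)  # internal-scale relative Cholesky
    z_scale: np.ndarray = field(repr=False)  # per-column standardization of Z
    x_scale: np.ndarray = field(repr=False)  # per-column standardization of X
    stats: _SuffStats = field(repr=False)  # built on X / x_scale and Z / z_scale
    diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def q(self) -> int:
        return self.re_cov.shape[0]

    def param_vcov(self) -> np.ndarray:
        p = self.fixed_estimates.size
        nv = self.vc_unconstrained.size
        V = np.zeros((p + nv, p + nv))
        V[:p, :p] = self.fixed_vcov
        if self.vc_vcov is not None:
            V[p:, p:] = self.vc_vcov
        return V

    def blup_frame(self) -> pd.DataFrame:
        cols = [f"b{k}" for k in range(self.q)]
        return pd.DataFrame(self.blups, columns=cols, index=pd.Index(self.group_ids, name="id"))

    def blups_at(self, beta: np.ndarray, gamma_internal: np.ndarray) -> np.ndarray:
        """BLUPs (original Z scale) under alternative parameter values.

        ``gamma_internal`` must be on the fit's internal standardized scale,
        e.g. a draw from :func:`sample_parameters`; ``beta`` is on the
        original (reporting) scale.
        """
        return compute_blups(self.stats, beta * self.x_scale, gamma_internal) / self.z_scale


@dataclass(frozen=True)
class LmmSpec:
    """Design builders mapping a long-format DataFrame to model matrices."""

    fixed_design: Callable[[pd.DataFrame], tuple[np.ndarray, list[str]]]
    random_design: Callable[[pd.DataFrame], np.ndarray]
    grouping: str = "id"
    response: str = "value"


@dataclass
class ParameterDraws:
    """Draws of the full parameter vector mapped back to the natural scale."""

    beta: np.ndarray     # (M, p)
    sigma: np.ndarray    # (M,)
    re_cov: np.ndarray   # (M, q, q)
    gamma: np.ndarray    # (M, q, q) relative Cholesky factors
    raw: np.ndarray      # (M, p + 1 + q(q+1)/2) on the estimation scale


# ---------------------------------------------------------------------------
# fitting


def compute_blups(stats: _SuffStats, beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Conditional-mean BLUPs b_i = Gamma A_i^-1 Gamma' Z_i'(y_i - X_i beta)."""
    q = stats.q
    W = np.einsum("ij,nik->njk", gamma, stats.ZtZ @ gamma)
    A = W + np.eye(q)
    g = stats.Zty - np.einsum("nip,p->ni", stats.ZtX, beta)
    Gg = np.einsum("ij,ni->nj", gamma, g)
    h = np.linalg.solve(A, Gg[:, :, None])[:, :, 0]
    return np.einsum("ij,nj->ni", gamma, h)


def fit_lmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    fixed_names: Sequence[str] | None = None,
    compute_vc_vcov: bool = True,
    start_gamma: np.ndarray | None = None,
    max_iter: int = 500,
) -> LmmFit:
    """ML fit from stacked design arrays.

    Parameters
    ----------
    start_gamma:
        Optional warm start for the relative Cholesky factor (q x q), e.g.
        the point-estimate solution when refitting inside a bootstrap.
    compute_vc_vcov:
        Whether to compute the observed-information covariance of the
        variance parameters (needed to sample them; skipped in inner
        bootstrap refits where only the fixed-effect covariance matters).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    p, q = X.shape[1], Z.shape[1]
    names = list(fixed_names) if fixed_names is not None else [f"x{j}" for j in range(p)]
    # standardize both designs internally so the GLS solves and the
    # relative-Cholesky optimization are well conditioned whatever the
    # column scales; estimates are mapped back before reporting
    z_scale = np.sqrt((Z**2).mean(axis=0))
    z_scale[z_scale == 0] = 1.0
    x_scale = np.sqrt((X**2).mean(axis=0))
    x_scale[x_scale == 0] = 1.0
    stats = _build_stats(y, X / x_scale, Z / z_scale, groups)
    if stats.n_groups < 2:
        raise ValueError("at least 2 subjects are required")

    il = np.tril_indices(q)
    if start_gamma is not None:
        x0 = np.asarray(start_gamma, dtype=float)[il]
    else:
        x0 = np.eye(q)[il] * 0.5

    def fun(vec):
        dev, grad, _, _ = _profiled_deviance(vec, stats, names, strict=False)
        return dev, grad

    if max_iter == 0:
        # evaluate at start_gamma without optimizing (L-BFGS-B always takes
        # at least one step, so this cannot be delegated to maxiter=0)
        if start_gamma is None:
            raise ValueError("max_iter=0 requires start_gamma")
        dev, grad, _, _ = _profiled_deviance(x0, stats, names)
        res = optimize.OptimizeResult(
            x=x0, fun=dev, jac=grad, nit=0, success=True,
            message="evaluated at start_gamma (max_iter=0)")
        return _finish_fit(res, stats, names, z_scale, x_scale,
                           compute_vc_vcov, converged=True)

    # ftol is relative: stop when the deviance improves by < ~1e-9 of its value
    opts = {"maxiter": max_iter, "ftol": 2e-9, "gtol": 1e-6}
    # Gamma entries are random-effect SDs relative to the residual SD; past
    # ~1e4 the Woodbury subtraction inside the profiled deviance cancels to
    # noise in double precision, so cap them there (the induced BLUP
    # shrinkage is O(1/ratio^2), negligible at the cap)
    bounds = [(-1e4, 1e4)] * x0.size
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    if not res.success and start_gamma is None:
        # one restart from a different scale before flagging non-convergence
        res2 = optimize.minimize(fun, np.eye(q)[il] * 0.05, jac=True,
                                 method="L-BFGS-B", bounds=bounds, options=opts)
        if res2.fun < res.fun:
            res = res2
    gnorm = float(np.max(np.abs(res.jac)))
    # L-BFGS-B sometimes stops with a line-search failure at what is, for the
    # deviance scale (O(n)), a fully converged point; accept a tiny gradient
    converged = bool(res.success) or gnorm < 1e-3 * max(1.0, abs(res.fun)) ** 0.5
    return _finish_fit(res, stats, names, z_scale, x_scale, compute_vc_vcov,
                       converged)


def _finish_fit(res, stats: _SuffStats, names, z_scale, x_scale,
                compute_vc_vcov: bool, converged: bool) -> "LmmFit":
    """Assemble an LmmFit from the optimizer state at ``res.x``."""
    q, p = stats.q, stats.p
    gnorm = float(np.max(np.abs(res.jac)))
    _, _, beta, rss = _profiled_deviance(res.x, stats, names)
    G = _gamma_from_vec(res.x, q)
    sigma2 = rss / stats.n_obs
    sigma = float(np.sqrt(sigma2))
    B = sigma2 * (G @ G.T)  # internal (standardized-Z) scale
    loglik = _loglik_at(stats, beta, sigma, _vc_unpack(_vc_pack(sigma, B), q)[2])

    # exact GLS covariance of beta: sigma^2 (X' V0^-1 X)^-1, mapped back
    # to the original column scale
    _, _, _, M, _, _ = _core_quantities(G, stats)
    fixed_vcov = sigma2 * np.linalg.inv(M) / np.outer(x_scale, x_scale)
    fixed_vcov = (fixed_vcov + fixed_vcov.T) / 2.0

    vc = _vc_pack(sigma, B)
    vc_vcov = None
    n_flat = 0
    if compute_vc_vcov:
        H = _numeric_hessian(lambda v: _loglik_at(stats, beta, *_vc_unpack(v, q)[::2]), vc)
        info = -(H + H.T) / 2.0
        # The likelihood can be essentially flat (or numerically indefinite)
        # along some covariance-parameter directions; there the quadratic
        # approximation carries no information and a plain inverse explodes.
        # Those directions are pinned at the estimate (zero sampling
        # variance) via a spectral floor rather than given garbage variance.
        w, Vec = np.linalg.eigh(info)
        floor = max(w.max(), 0.0) * 1e-6
        keep = w > floor
        n_flat = int((~keep).sum())
        w_inv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
        vc_vcov = (Vec * w_inv) @ Vec.T
        vc_vcov, n_trimmed = _calibrate_vc_vcov(stats, beta, vc, vc_vcov)
        n_flat += n_trimmed

    blups = compute_blups(stats, beta, G) / z_scale
    n_params = p + 1 + q * (q + 1) // 2
    fit = LmmFit(
        fixed_names=names,
        fixed_estimates=beta / x_scale,
        fixed_vcov=fixed_vcov,
        re_cov=B / np.outer(z_scale, z_scale),
        resid_sd=sigma,
        vc_unconstrained=vc,
        vc_vcov=vc_vcov,
        loglik=float(loglik),
        n_params=n_params,
        converged=converged,
        n_obs=stats.n_obs,
        n_subjects=stats.n_groups,
        group_ids=stats.group_ids,
        blups=blups,
        gamma=G,
        z_scale=z_scale,
        x_scale=x_scale,
        stats=stats,
        diagnostics={"n_iter": int(res.nit), "grad_norm": gnorm,
                     "message": str(res.message), "n_flat_vc": n_flat},
    )
    if not converged:
        warnings.warn(f"mixed-model fit did not converge: {res.message}", stacklevel=2)
    return fit


def fit_lmm(panel: pd.DataFrame, spec: LmmSpec, **kwargs) -> LmmFit:
    """Fit a linear mixed model from a long-format panel and design builders."""
    X, names = spec.fixed_design(panel)
    Z = spec.random_design(panel)
    return fit_lmm_arrays(
        panel[spec.response].to_numpy(float), X, Z,
        panel[spec.grouping].to_numpy(), fixed_names=names, **kwargs,
    )


def blup(fit: LmmFit, subject_id) -> np.ndarray:
    """Predicted random-effect vector for one subject of the fitted panel."""
    idx = np.flatnonzero(fit.group_ids == subject_id)
    if idx.size == 0:
        raise UnknownSubjectError(f"subject {subject_id!r} not in fitted panel")
    return fit.blups[idx[0]].copy()


def sample_parameters(fit: LmmFit, n_draws: int, seed=None) -> ParameterDraws:
    """Draw full parameter vectors from the asymptotic Gaussian.

    Draws are Gaussian on the estimation scale (beta, sigma, Cholesky of
    B) centered at the estimate with the covariance from
    :meth:`LmmFit.param_vcov`, then mapped back; any Cholesky draw yields
    a PSD random-effect covariance and the residual SD enters through its
    absolute value.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = fit.fixed_estimates.size
    q = fit.q
    center = np.concatenate([fit.fixed_estimates, fit.vc_unconstrained])
    V = _psd_clip(fit.param_vcov())
    w, Vec = np.linalg.eigh(V)
    root = Vec * np.sqrt(np.clip(w, 0.0, None))
    raw = center + rng.standard_normal((n_draws, center.size)) @ root.T
    beta = raw[:, :p]
    sigma = np.empty(n_draws)
    re_cov = np.empty((n_draws, q, q))
    gamma = np.empty((n_draws, q, q))
    scale_outer = np.outer(fit.z_scale, fit.z_scale)
    for m in range(n_draws):
        s, B, L = _vc_unpack(raw[m, p:], q)
        sigma[m] = s
        re_cov[m] = B / scale_outer          # original Z scale
        gamma[m] = L / s                     # internal scale, for blups_at
    return ParameterDraws(beta=beta, sigma=sigma, re_cov=re_cov, gamma=gamma, raw=raw)
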