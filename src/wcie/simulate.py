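"""Simulation framework: generate cohorts with known weight functions.

A cohort consists of an intermittently measured, error-prone exposure on
the retrospective window [-S, 0] and a post-landmark outcome whose level
and slope depend on the true (error-free) exposure history through known
weight functions.  Three shapes are provided:

* Scenario A — constant weights (every past year matters equally),
* Scenario B — smooth recency profile: remote exposure matters, the
  effect fades to zero towards the landmark,
* Scenario C — a sign-changing profile (remote exposure harmful, recent
  exposure protective) tabulated on a few anchor points and linearly
  interpolated.

``run_simulation_study`` repeatedly generates cohorts, runs the full
two-stage pipeline, and reports bias, empirical SD and CI coverage of
the estimated trajectories against the generating truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from wcie.bases import NATURAL_CUBIC, BasisSpec, make_basis
from wcie.estimator import LandmarkWCIE

__all__ = [
    "ScenarioSpec",
    "CohortTruth",
    "SimulationReport",
    "scenario_weights",
    "generate_cohort",
    "run_simulation_study",
]


# ---------------------------------------------------------------------------
# scenario weight functions


_C_LEVEL_T = np.array([-24.0, -20.0, -16.0, -12.0, -8.0, -5.0, -2.0, 0.0])
_C_LEVEL_V = np.array([-0.025, -0.010, 0.000, -0.008, -0.012, -0.005, 0.012, 0.020])
_C_SLOPE_T = np.array([-24.0, -16.0, -13.0, -10.0, -8.0, -5.0, -2.0, 0.0])
_C_SLOPE_V = np.array([0.0, 0.0, 0.0, -0.002, -0.003, 0.0, 0.002, 0.003])


def scenario_weights(scenario: str, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """True weight functions (w_I, w_S) evaluated at times t in [-S, 0]."""
    t = np.asarray(t, dtype=float)
    if scenario == "A":
        return np.full(t.shape, -0.05), np.full(t.shape, -0.01)
    if scenario == "B":
        shape = sps.norm.cdf((t + 24.0) / 6.0) - 1.0
        return shape * 0.1, shape * 0.03
    if scenario == "C":
        return (np.interp(t, _C_LEVEL_T, _C_LEVEL_V),
                np.interp(t, _C_SLOPE_T, _C_SLOPE_V))
    raise ValueError(f"unknown scenario {scenario!r}; expected 'A', 'B' or 'C'")


# ---------------------------------------------------------------------------
# cohort specification


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating parameters of a simulated cohort.

    The defaults are the main design: 13 theoretical exposure visits every
    2 years on [-24, 0] with jitter and 10% missed visits, measurement
    error SD 0.9, and 4 outcome visits at 0/2/4/6 years.  The sensitivity
    knobs are visit spacing, missingness, the error SD, and a heavy-tailed
    (Cauchy) measurement-error distribution whose location can be shifted
    to make the error non-centered.
    """

    scenario: str = "A"
    n_subjects: int = 500
    window: float = 24.0
    # exposure design
    exposure_spacing: float = 2.0
    exposure_jitter: float = 0.5
    missing_exposure: float = 0.10
    sigma_eps: float = 0.9
    error_dist: str = "normal"          # "normal" | "cauchy"
    cauchy_loc: float = 0.0
    cauchy_scale: float = 0.7
    # outcome design
    outcome_visits: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    outcome_jitter: float = 0.5
    missing_outcome: float = 0.03
    # exposure trajectory model
    exposure_level: float = 27.0        # population mean at the landmark
    exposure_drift: float = 0.104       # mean increase per year
    beta_age: float = 0.02
    beta_edu: float = -0.3
    sd_intercept: float = 3.5
    sd_slope: float = 0.08
    corr_int_slope: float = 0.3
    sd_curvature: float = 0.7
    n_curvature: int = 4
    # outcome model
    alpha0: float = 33.7
    alpha_slope: float = -0.2
    alpha_age_level: float = -0.1
    alpha_edu_level: float = 0.8
    alpha_age_slope: float = -0.01
    alpha_edu_slope: float = 0.05
    alpha_v0: float = -0.3
    sd_out_intercept: float = 2.0
    sd_out_slope: float = 0.25
    corr_out: float = -0.2
    sigma_outcome: float = 1.4

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.error_dist not in ("normal", "cauchy"):
            raise ValueError('error_dist must be "normal" or "cauchy"')
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


@dataclass
class CohortTruth:
    """What the generator knows: true histories and weight functions."""

    grid: np.ndarray
    subject_ids: np.ndarray
    U_true: np.ndarray              # (N, G) error-free exposure on the grid
    w_level: np.ndarray             # true w_I on the grid
    w_slope: np.ndarray             # true w_S on the grid
    wcie_level: np.ndarray          # per-subject true weighted index (level)
    wcie_slope: np.ndarray
    spec: ScenarioSpec = field(repr=False)


def _curvature_features(spec: ScenarioSpec, t: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Unit-RMS curvature columns of a natural cubic spline of time."""
    S = spec.window
    knots = -S + S * np.arange(1, spec.n_curvature + 1) / (spec.n_curvature + 1)
    bspec = BasisSpec(NATURAL_CUBIC, tuple(knots), (-S, 0.0))
    cols = make_basis(bspec, t).values[:, 1:]              # drop the linear column
    ref = make_basis(bspec, grid).values[:, 1:]
    rms = np.sqrt(np.mean(ref**2, axis=0))
    return cols / rms


def generate_cohort(spec: ScenarioSpec, seed) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate one cohort: (exposure panel, outcome panel, truth bundle)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects
    S = spec.window
    grid = np.arange(-S, 0.5, 1.0)
    ids = np.arange(1, n + 1)

    age0 = rng.normal(51.0, 3.0, n)
    edu = rng.binomial(1, 0.25, n).astype(float)

    # subject-level random trajectory coefficients
    cov_is = np.array([
        [spec.sd_intercept**2, spec.corr_int_slope * spec.sd_intercept * spec.sd_slope],
        [spec.corr_int_slope * spec.sd_intercept * spec.sd_slope, spec.sd_slope**2],
    ])
    b_is = rng.multivariate_normal(np.zeros(2), cov_is, size=n)
    b_curv = rng.normal(0.0, spec.sd_curvature, size=(n, spec.n_curvature))

    def true_exposure(t: np.ndarray) -> np.ndarray:
        """Error-free exposure for all subjects at shared times t -> (N, len(t))."""
        mu = spec.exposure_level + spec.exposure_drift * t
        fixed = (mu[None, :]
                 + spec.beta_age * (age0 - 51.0)[:, None]
                 + spec.beta_edu * edu[:, None])
        Phi = _curvature_features(spec, t, grid)           # (len(t), n_curv)
        return (fixed
                + b_is[:, [0]]
                + b_is[:, [1]] * t[None, :]
                + b_curv @ Phi.T)

    def true_exposure_rows(sub: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Error-free exposure for observation rows (subject index, time)."""
        Phi = _curvature_features(spec, t, grid)           # (len(t), n_curv)
        return (spec.exposure_level + spec.exposure_drift * t
                + spec.beta_age * (age0[sub] - 51.0)
                + spec.beta_edu * edu[sub]
                + b_is[sub, 0] + b_is[sub, 1] * t
                + np.einsum("rk,rk->r", b_curv[sub], Phi))

    U_true = true_exposure(grid)                           # (N, G)
    w_level, w_slope = scenario_weights(spec.scenario, grid)
    wcie_level = U_true @ w_level
    wcie_slope = U_true @ w_slope
    # center against the population-mean history so the outcome intercept
    # and slope keep their nominal values regardless of the scenario
    mu_pop = (spec.exposure_level + spec.exposure_drift * grid
              + spec.beta_edu * 0.25)
    center_level = float(mu_pop @ w_level)
    center_slope = float(mu_pop @ w_slope)

    # ---------------- exposure panel ----------------
    theoretical = np.arange(-S, 0.5, spec.exposure_spacing)
    n_vis = theoretical.size
    times = theoretical[None, :] + rng.uniform(-spec.exposure_jitter,
                                               spec.exposure_jitter, (n, n_vis))
    times = np.clip(times, -S, 0.0)
    keep = rng.uniform(size=(n, n_vis)) >= spec.missing_exposure
    # never drop a subject's entire history
    empty = ~keep.any(axis=1)
    keep[empty, 0] = True

    sub_idx, vis_idx = np.nonzero(keep)
    exp_id = ids[sub_idx]
    exp_t = times[sub_idx, vis_idx]
    exp_u = true_exposure_rows(sub_idx, exp_t)
    if spec.error_dist == "normal":
        eps = rng.normal(0.0, spec.sigma_eps, exp_u.size)
    else:
        eps = spec.cauchy_loc + spec.cauchy_scale * rng.standard_cauchy(exp_u.size)
    exposure = pd.DataFrame({
        "id": exp_id, "time": exp_t, "value": exp_u + eps,
        "age0": age0[sub_idx], "education": edu[sub_idx],
    }).sort_values(["id", "time"], kind="stable").reset_index(drop=True)

    # ---------------- outcome panel ----------------
    cov_out = np.array([
        [spec.sd_out_intercept**2, spec.corr_out * spec.sd_out_intercept * spec.sd_out_slope],
        [spec.corr_out * spec.sd_out_intercept * spec.sd_out_slope, spec.sd_out_slope**2],
    ])
    c = rng.multivariate_normal(np.zeros(2), cov_out, size=n)
    level = (spec.alpha0
             + spec.alpha_age_level * (age0 - 51.0)
             + spec.alpha_edu_level * edu
             + (wcie_level - center_level)
             + c[:, 0])
    slope = (spec.alpha_slope
             + spec.alpha_age_slope * (age0 - 51.0)
             + spec.alpha_edu_slope * edu
             + (wcie_slope - center_slope)
             + c[:, 1])

    visits = np.asarray(spec.outcome_visits, dtype=float)
    n_ov = visits.size
    ot = visits[None, :] + rng.uniform(-spec.outcome_jitter, spec.outcome_jitter, (n, n_ov))
    ot = np.clip(ot, 0.0, None)
    keep_o = rng.uniform(size=(n, n_ov)) >= spec.missing_outcome
    empty = ~keep_o.any(axis=1)
    keep_o[empty, 0] = True

    # rows in subject-major, visit order; jitter < spacing/2 keeps times sorted
    sub_o, vis_o = np.nonzero(keep_o)
    t_o = ot[sub_o, vis_o]
    v0 = np.zeros(t_o.size)
    v0[np.unique(sub_o, return_index=True)[1]] = 1.0       # first kept visit
    y_o = (level[sub_o] + slope[sub_o] * t_o + spec.alpha_v0 * v0
           + rng.normal(0.0, spec.sigma_outcome, t_o.size))
    outcome = pd.DataFrame({
        "id": ids[sub_o], "time": t_o, "value": y_o, "V0": v0,
        "age0": age0[sub_o], "education": edu[sub_o],
    })

    truth = CohortTruth(grid=grid, subject_ids=ids, U_true=U_true,
                        w_level=w_level, w_slope=w_slope,
                        wcie_level=wcie_level, wcie_slope=wcie_slope, spec=spec)
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# simulation study


@dataclass
class SimulationReport:
    """Replicate-aggregated operating characteristics of the pipeline."""

    frame: pd.DataFrame           # t_U x component: truth, bias, emp_sd, coverage
    scenario: str
    n_reps: int
    n_converged: int
    n_failed: int
    stage1_resid_sd: np.ndarray   # per-replicate sigma_eps estimates
    spec: ScenarioSpec = field(repr=False)


def run_simulation_study(
    spec: ScenarioSpec,
    n_reps: int,
    seed,
    n_bootstrap: int = 0,
    bootstrap_param_set: str = "all",
    weight_knot_candidates=(2,),
    ci_level: float = 0.95,
    include_v0: bool = True,
    max_failure_fraction: float = 0.10,
) -> SimulationReport:
    """Generate ``n_reps`` cohorts, fit the pipeline, aggregate bias/SD/coverage.

    Coverage is only populated when ``n_bootstrap > 0`` (the CIs then use
    the bootstrap total variance); otherwise the naive stage-2 CIs are
    assessed.  Replicates whose fit raises are dropped, up to
    ``max_failure_fraction`` of the total.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (empirical SDs need replication)")
    if n_reps < 10:
        warnings.warn(
            f"only {n_reps} replicates: bias/SD/coverage estimates will be unstable",
            stacklevel=2,
        )
    children = np.random.SeedSequence(seed).spawn(n_reps)
    grid = np.arange(-spec.window, 0.5, 1.0)
    w_level, w_slope = scenario_weights(spec.scenario, grid)

    est_level, est_slope = [], []
    cov_level, cov_slope = [], []
    sigmas = []
    n_failed = 0
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        exposure, outcome, _ = generate_cohort(spec, rng)
        model = LandmarkWCIE(
            window=spec.window,
            confounders=("age0", "education"),
            include_v0=include_v0,
            weight_knot_candidates=weight_knot_candidates,
            n_bootstrap=n_bootstrap,
            bootstrap_param_set=bootstrap_param_set,
            ci_level=ci_level,
            random_state=rng,
        )
        try:
            model.fit(exposure, outcome)
        except (np.linalg.LinAlgError, RuntimeError, ValueError):
            n_failed += 1
            continue
        traj = model.trajectory_
        est_level.append(traj.level_effect)
        est_slope.append(traj.slope_effect)
        sigmas.append(model.exposure_model_.lmm_.resid_sd)
        if traj.level_var is not None:
            z = sps.norm.ppf(0.5 + ci_level / 2.0)
            half_l = z * traj.level_se
            half_s = z * traj.slope_se
            cov_level.append(np.abs(traj.level_effect - w_level) <= half_l)
            cov_slope.append(np.abs(traj.slope_effect - w_slope) <= half_s)

    if n_failed > max_failure_fraction * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} simulation replicates failed "
            f"(limit {max_failure_fraction:.0%})"
        )
    L = np.asarray(est_level)
    Sl = np.asarray(est_slope)
    rows = []
    for comp, truth_vals, est, covs in (
        ("level", w_level, L, cov_level),
        ("slope", w_slope, Sl, cov_slope),
    ):
        mean_est = est.mean(axis=0)
        emp_sd = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.full(grid.size, np.nan)
        coverage = (np.asarray(covs).mean(axis=0) if covs
                    else np.full(grid.size, np.nan))
        rows.append(pd.DataFrame({
            "t_U": grid, "component": comp, "truth": truth_vals,
            "mean_estimate": mean_est, "bias": mean_est - truth_vals,
            "emp_sd": emp_sd, "coverage": coverage,
        }))
    return SimulationReport(
        frame=pd.concat(rows, ignore_index=True),
        scenario=spec.scenario,
        n_reps=n_reps,
        n_converged=L.shape[0],
        n_failed=n_failed,
        stage1_resid_sd=np.asarray(sigmas),
        spec=spec,
    )
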