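"""Shared fixtures: small simulated cohorts and fitted pipeline pieces."""

import numpy as np
import pytest

from wcie.exposure import ExposureHistoryModel
from wcie.simulate import ScenarioSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 150-subject Scenario A cohort."""
    spec = ScenarioSpec(scenario="A", n_subjects=150)
    exposure, outcome, truth = generate_cohort(spec, seed=20240713)
    return exposure, outcome, truth


@pytest.fixture(scope="session")
def fitted_exposure(small_cohort):
    """Stage-1 fit (with the variance-parameter covariance) on the cohort."""
    exposure, _, _ = small_cohort
    return ExposureHistoryModel(compute_vcov=True).fit(exposure)


@pytest.fixture(scope="session")
def predicted(fitted_exposure):
    return fitted_exposure.predict_history()


def make_longitudinal(seed=0, n=60, q_cols=2, sigma=0.8):
    """Small random-intercept(+slope) panel with known generating values."""
    rng = np.random.default_rng(seed)
    n_vis = 5
    t = np.tile(np.arange(n_vis, dtype=float), n)
    ids = np.repeat(np.arange(n), n_vis)
    x1 = rng.normal(size=n * n_vis)
    X = np.column_stack([np.ones(n * n_vis), t, x1])
    B = np.array([[1.0, 0.3], [0.3, 0.25]])[:q_cols, :q_cols]
    b = rng.multivariate_normal(np.zeros(q_cols), B, size=n)
    Z = np.column_stack([np.ones(n * n_vis), t])[:, :q_cols]
    beta = np.array([2.0, -0.5, 1.0])
    y = X @ beta + np.einsum("rj,rj->r", Z, b[ids]) + rng.normal(0, sigma, n * n_vis)
    return y, X, Z, ids, beta, B, sigma
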