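# wcie

Landmark weighted cumulative index of exposure (WCIE) for longitudinal
outcomes.

The package estimates how an error-prone, irregularly measured exposure
accumulated over a retrospective window `[-S, 0]` is associated with the
level and the slope of a longitudinal outcome observed from the landmark
(time 0) onward. It implements a two-stage regression-calibration approach:

1. **Stage 1** — a linear mixed model with a natural cubic spline mean and
   subject-level random effects is fitted to the observed exposure
   measurements; best linear unbiased predictions (BLUPs) reconstruct each
   subject's error-free exposure history on a yearly grid.
2. **Stage 2** — the histories are summarized as weighted cumulative
   indices `H_ik = sum_t B_k(t) U_i(t)` for a spline weight basis `B`, and
   these enter a linear mixed model for the outcome on both the intercept
   (level) and the time slope. The time-varying association
   `gamma(t) = sum_k theta_k B_k(t)` is reported with delta-method or
   parametric-bootstrap confidence bands; the bootstrap propagates stage-1
   estimation uncertainty by redrawing the stage-1 parameters from their
   asymptotic distribution and combining the within- and between-draw
   covariance of the stage-2 coefficients.

The weight basis is chosen by AIC among natural-cubic-spline candidates
with a configurable number of inner knots.

## Quick start

```python
from wcie import LandmarkWCIE
from wcie.simulate import ScenarioSpec, generate_cohort

exposure, outcome, truth = generate_cohort(
    ScenarioSpec(scenario="B", n_subjects=500), seed=1)

model = LandmarkWCIE(weight_knot_candidates=(1, 2, 3),
                     n_bootstrap=200, random_state=1).fit(exposure, outcome)

model.trajectory_frame()      # tidy frame: t_U, estimates, CIs
model.overall_mean_level_     # grid-averaged level association
model.aic_table_              # the weight-basis selection table
```

Input panels are long-format data frames. The exposure panel needs columns
`id, time, value` plus the baseline confounders (`time` in `[-S, 0]`); the
outcome panel needs `id, time, value` plus confounders (`time >= 0`) and
optionally a first-visit indicator `V0`.

## Command line

```bash
wcie simulate --scenario B --n-subjects 500 --seed 1 --out data/
wcie fit --exposure data/exposure.csv --outcome data/outcome.csv \
         --config run.yaml --out results/
wcie study --scenario A --n-reps 100 --n-subjects 500 --out report.csv
```

`wcie fit` writes the trajectory with confidence bands, the resolved
configuration, and a run log (seed, config hash, selection table) for
reproducibility.

## Layout

| Module | Contents |
| --- | --- |
| `wcie.bases` | natural cubic spline / piecewise weight bases, knot placement |
| `wcie.lmm` | maximum-likelihood linear mixed model, BLUPs, parameter sampling |
| `wcie.exposure` | stage-1 exposure history model |
| `wcie.history` | weighted cumulative history covariates |
| `wcie.outcome` | stage-2 outcome model, AIC selection, association trajectory |
| `wcie.bootstrap` | parametric bootstrap of the total variance |
| `wcie.estimator` | `LandmarkWCIE`, the end-to-end estimator |
| `wcie.simulate` | scenario generator and simulation-study runner |
| `wcie.config`, `wcie.cli` | YAML run configuration and the `wcie` CLI |

See `docs/methods.md` for the statistical details and the numerical
decisions (internal design standardization, the sampling scale of the
variance parameters, degenerate weight bases).

## Tests

```bash
python -m pytest -q                   # unit + acceptance suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script runs scaled-down operating-characteristic studies
(bootstrap coverage, bias of the recovered associations, residual-SD
recovery) and writes the summary statistics as JSON.
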