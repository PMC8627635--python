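# Methods

This note records the statistical model the package implements and the
numerical decisions that a reader of the results should know about.

## Model

### Stage 1: exposure history

For subject `i` with exposure measurements `X_ij` at times
`t_ij` in `[-S, 0]` (the landmark is 0):

```
X_ij = F(t_ij)' beta + age0_i b_a + edu_i b_e + b_0i + F(t_ij)' b_1i + eps_ij
```

where `F` is a natural cubic spline basis over `[-S, 0]`,
`(b_0i, b_1i) ~ N(0, B)` and `eps_ij ~ N(0, sigma_eps^2)`. The model is
fitted by maximum likelihood; the error-free history is reconstructed on a
yearly grid `t = -S, ..., 0` from the BLUPs:

```
U_i(t) = F(t)' beta + covariates_i' beta_cov + b_0i + F(t)' b_1i .
```

Random-effects structure is configurable (`intercept`, `slope`, `spline`);
the default puts random effects on the full spline basis, which is what
identifies weight functions with more than two coefficients (with only a
random intercept and slope the subject-level variation of the histories is
two-dimensional, and any weight basis with more than two columns is
rank-deficient in stage 2 given the confounders).

### Stage 2: outcome model and the weighted cumulative index

Given a weight basis `B_1..B_K` on `[-S, 0]`, the history summaries are

```
H_ik = sum_{t in grid} B_k(t) U_i(t)        ("discrete-sum", default)
```

(or a trapezoidal quadrature). The outcome model is a linear mixed model
with subject random intercept and slope:

```
Y_ij = (mu_0 + H_i' theta_I + conf_i' delta_0 [+ nu V0_ij])
     + (mu_1 + H_i' theta_S + conf_i' delta_1) * t_ij
     + u_0i + u_1i t_ij + e_ij .
```

The time-varying association of exposure at history time `t` with the
outcome level and slope is

```
gamma_I(t) = sum_k theta_Ik B_k(t),    gamma_S(t) = sum_k theta_Sk B_k(t),
```

with pointwise variance `B(t)' V B(t)` (delta method) where `V` is the
covariance of the corresponding `theta` block. The "overall mean" effect is
the grid average of the trajectory. The weight basis (number of inner
knots) is selected by AIC across candidates refitted on the same data;
ties go to the smaller basis.

### Total variance via parametric bootstrap

The naive stage-2 covariance ignores that `H` is built from estimated
stage-1 parameters. The parametric bootstrap redraws the full stage-1
parameter vector `phi_U` (fixed effects, residual SD, random-effect
covariance) from its asymptotic Gaussian, rebuilds the BLUP histories and
`H`, refits stage 2, and combines

```
V_tot = (1/M) sum_m V_intra_m  +  (1/M) sum_m (phi_m - phi_bar)(phi_m - phi_bar)'
```

where `V_intra_m` is the exact GLS covariance of the stage-2 fixed effects
in draw `m`. With `M = 1` the between term is identically zero and
`V_tot = V_intra`. A `denominator="M-1"` variant and a
`param_set="fixed"` variant (perturb only the stage-1 fixed effects) are
available as diagnostics.

## Numerical decisions

These are implementation choices that matter for reproducing results; each
is exercised by a dedicated test.

**Internal design standardization.** Inside the mixed-model fitter both
the fixed design `X` and the random design `Z` are standardized
column-wise (root-mean-square scaling); estimates, covariances and BLUPs
are mapped back to the data scale. WCIE history columns are strongly
correlated and span orders of magnitude, and the raw GLS normal equations
can reach condition numbers ~5e19 versus ~3e14 after equilibration.

**Bounded relative Cholesky.** The covariance is optimized as a
"relative Cholesky" factor `Gamma` with `B = sigma^2 Gamma Gamma'`. Entries
of `Gamma` are random-effect SDs relative to the residual SD; beyond a
ratio of ~1e4 the Woodbury subtraction inside the profiled deviance cancels
below double precision, so the optimizer bounds `|Gamma| <= 1e4`. At the
bound the induced BLUP shrinkage is O(1/ratio^2), i.e. negligible; the cap
is a conditioning guard, not a prior. (It is what allows a noise-free,
densely sampled exposure panel to be reproduced by the BLUPs to ~1e-6.)

**Sampling scale of the variance parameters.** Stage-1 parameter draws for
the bootstrap are Gaussian on the raw Cholesky scale
`[sigma, vech(chol(B))]`, not a log-diagonal scale: every draw maps to a
valid PSD covariance, and the back-transformation is not skewed (a
log-diagonal scale back-transforms lognormally, which inflates the
bootstrap variance and distorts coverage). The observed information for
these parameters can be flat or indefinite along some directions
(boundary-like fits); such directions are pinned at the estimate via a
spectral floor, and every eigendirection of the draw covariance is
calibrated against the actual likelihood drop it produces, shrinking
directions whose quadratic approximation understates the drop.

**Degenerate weight bases.** Zero inner knots is allowed: the natural
cubic spline degenerates to a linear-in-time weight and the piecewise
basis to a single constant weight (a plain cumulative index). The constant
basis is the minimal member of the candidate family and is useful both as
a baseline and in severe-misspecification diagnostics, where larger bases
can become numerically unidentified.

**Identifiability convention.** The exposure coefficients inside the level
and slope submodels are absorbed into the weight functions (the overall
multipliers are fixed to 1); only `gamma_I(t)` and `gamma_S(t)` are
reported.

**Evaluating at fixed variance parameters.** `fit_lmm_arrays(...,
start_gamma=g, max_iter=0)` assembles the full fit (GLS fixed effects,
covariances, BLUPs) at the supplied variance parameters without
optimizing. This is used to verify exact algebraic identities, e.g. that
an invertible reparameterization of the weight basis leaves the fitted
trajectory unchanged.

## Simulation framework

`wcie.simulate` generates cohorts with 13 scheduled exposure visits on
`[-24, 0]` (2-yearly, jittered, 10% missing), outcome visits at 0/2/4/6,
exposure measurement error SD 0.9, and three weight scenarios:

- **A** — constant weights (level -0.05, slope -0.01);
- **B** — smooth recency profile, largest in the remote past and fading to
  0 at the landmark;
- **C** — a sign-changing curve (remote negative, recent positive),
  shipped as a clearly labeled synthetic tabulated curve.

A sensitivity option replaces the Gaussian measurement error with
Cauchy(loc, 0.7) to probe robustness; under this contamination the
Gaussian stage-1 likelihood degenerates and the method is strongly
attenuated (this is asserted, as a negative control, in the acceptance
tests). `run_simulation_study` runs replicate fits, reports bias,
empirical SD and pointwise CI coverage of the trajectories, requires at
least 2 replicates and warns below 10.
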