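# Methods

## The analysis model

All per-metabolite inference rests on single-random-intercept mixed
models. For a continuous response (DAS28-CRP in the association scan,
metabolite abundance in the treatment / CRP / visit-change scans):

    y_ij = x_ij' beta + u_i + e_ij,  u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

with patient `i`, sample `j`. Variance components are estimated by
restricted maximum likelihood (REML): the criterion is profiled to a
one-dimensional function of the variance ratio `theta =
sigma_u^2/sigma_e^2` and maximized by golden-section search on
`log(theta)` over [e-12, e8] (60 iterations, interval precision far
below the 1e-8 deviance tolerance), with an explicit comparison against
the `theta = 0` boundary. At the boundary the fit is exactly ordinary
least squares and the residual degrees of freedom are `n - p`.

Fixed-effect p-values use t statistics with Satterthwaite effective
degrees of freedom

    nu_j = 2 Var(beta_j)^2 / (g_j' W g_j),

where `g_j` is the gradient of `Var(beta_j)` with respect to
`(sigma_u^2, sigma_e^2)` and `W` the inverse observed REML information,
both obtained by central finite differences (relative step 1e-4) of the
unprofiled REML log-likelihood. `nu` is clamped to `[1, n - p]` and
falls back to `n - p` whenever the information matrix is not positive
definite or the variance sits at the boundary. Against lmerTest the
implementation agrees to ~7 significant figures in coefficients,
standard errors, df and p-values on a reference fit (frozen in the test
suite).

For the dichotomized activity-group response the model is a
random-intercept logistic regression estimated by maximum likelihood
with a Laplace approximation: per-group posterior modes by damped
Newton (vectorized across groups), the marginal likelihood maximized
over `(beta, log sigma_u^2)` by L-BFGS-B with the exact gradient of the
Laplace objective (envelope theorem plus implicit differentiation of
the modes and of the curvature in the log-determinant term). Inference
is Wald z from the observed information; no df correction is applied.
Because the Laplace objective equals the exact likelihood at
`sigma_u^2 = 0`, a sub-1e-3 likelihood "gain" at small positive
variance is treated as approximation error and the boundary (plain
logistic) fit is returned instead; with one Bernoulli observation per
group the intercept variance is not meaningfully identifiable and the
Laplace approximation is unreliable there, so singleton-only groupings
are fit directly at the boundary. Perfect separation is reported via
`converged = False`, never as silent coefficients. The implementation
matches `lme4::glmer` (nAGQ = 1) to ~4 decimals on a frozen reference
fit.

A batched path (`lmm_scan`) fits all metabolites of a scan
simultaneously: the profiled REML criterion only needs `X'X`, `X'y`,
`y'y` and per-group sums, so a metabolome-wide scan is a sequence of
O(60) vectorized evaluations rather than 686 independent optimizations.
A full 686-metabolite linear scan takes well under a second; the
logistic scan fits per metabolite (~10 ms each).

## Scan definitions and conventions

- Activity groups: lower = DAS28-CRP <= 3.2, higher > 3.2 (the boundary
  belongs to lower). CRP groups: low <= 3.0 mg/L < high.
- Adjustment covariates default to age + sex; the confounder screen
  (Fisher exact on dichotomized covariates vs activity group, exact
  McNemar for paired visit-1/visit-2 treatment use, Wilcoxon signed-rank
  for paired DAS28-CRP) re-derives the set per run so synthetic cohorts
  adapt. Covariates constant within an analyzed subset are dropped from
  the design (they are inestimable there).
- Sex is coded female = 0 / male = 1, smoking ever = 1 / never = 0, age
  in years untransformed, so coefficients are comparable across runs.
- Hit sets use raw p < 0.05 per coefficient, no multiplicity
  correction; a Benjamini-Hochberg column is available behind a flag
  and off by default.
- Fold change is `log2(mean_higher / mean_lower)` over scaled-imputed
  values (arithmetic group means).
- Pathway enrichment is the exact hypergeometric upper tail
  `P(X >= k)` with fold enrichment `(k/n)/(K/N)`.
- The two-stage CRP analysis screens each candidate covariate
  marginally against abundance; the CRP-group term always enters the
  adjusted model whether or not its own screen was significant,
  otherwise the final test would be undefined.
- EULAR response uses the conventional grid (good: improvement > 1.2
  and attained <= 3.2; moderate: improvement > 1.2 with attained > 3.2,
  or improvement in (0.6, 1.2] with attained <= 5.1); the cut-points are
  exposed as arguments because DAS28-CRP-specific adaptations differ.

## Prediction

The GLM of DAS28-CRP on metabolite abundances is Gaussian with identity
link (the response is continuous). With feature selection, the
predictors are the metabolites passing the association scan at p <
0.05. Without selection, all metabolites enter and, since p >> n, the
fit is defined as the minimum-norm least-squares solution via the
pseudoinverse — deterministic and hyperparameter-free; any ridge-like
choice would change this baseline and is deliberately avoided.
Predictions are not clipped to the DAS28-CRP range; negative
predictions are reported as such.

Cross-validation holds out all samples of one patient per fold (fold
order = patient ID sort order, no randomness). Feature selection runs
inside each fold on the training patients only; the test suite asserts
that each fold's features equal an independent re-scan of its training
subset, i.e. the held-out patient can never influence the features used
to predict them. Validation-cohort evaluation reports MAE, the SD of
absolute errors, and Spearman's rho with a two-sided t-approximation
p-value (n - 2 df) and a 95% CI by Fisher z-transform with SE
1/sqrt(n - 3).

## The synthetic cohort generator

The generator emulates a two-visit discovery cohort (default 64
patients, 128 samples) plus a 12-patient single-visit validation
cohort, 686 metabolites:

- Abundances are per-metabolite log-normal; the log-scale SD defaults
  to 0.8, giving the heavy-tailed intensity distributions typical of
  untargeted platforms. This dispersion matters: with thin-tailed
  predictors the minimum-norm interpolator behaves benignly and the
  with/without-selection contrast in cross-validation disappears,
  whereas heavy tails reproduce the overfitting that feature selection
  protects against.
- A sparse set of metabolites (default 5) carries linear effects on
  DAS28-CRP, applied to abundances divided by their discovery-cohort
  medians (the scale the preprocessing reproduces). Effects have fixed
  magnitude `effect_size_sd` (default 0.8 DAS28-CRP units per unit
  scaled abundance) with random sign, the standard design for recovery
  and power simulations — draws from a zero-centered distribution would
  label near-zero effects "causal" and blur the ground truth. The
  coefficient SD still equals `effect_size_sd`.
- DAS28-CRP adds a patient random intercept (SD 0.8), small age/sex
  terms, residual noise (SD 0.5), and is clipped to the score's
  observed range [1.2, 7.0]. Clipping is simpler than resampling but
  biases the linear model at the extremes; experiments that need an
  exactly linear generative model (coefficient recovery, CI coverage)
  widen the range instead of disabling the mechanism.
- CRP is `max(0.1, exp(-0.8 + 0.55 * DAS28 + noise))` mg/L — a noisy
  monotone coupling chosen so CRP-group analyses carry signal and the
  high/low split lands near the cohort's observed proportions; no
  empirical joint distribution is claimed.
- Demographics follow the emulated cohort: ~69% female, age ~N(63,
  10.5), BMI ~N(30.8, 5.5), 60% ever-smokers, treatment frequencies
  75/45/31/36/9% for methotrexate, prednisone, non-MTX csDMARDs,
  TNFi-bDMARDs, non-TNFi-bDMARDs, mostly stable across visits (3%
  switch probability keeps the McNemar screen exercisable).
- Missingness is left-censoring at the per-metabolite quantile
  (detection limit), matching the minimum-value imputation rationale:
  by default 25% of metabolites are censored at the 10% quantile and a
  further 3% at the 30% quantile so the >20% filter has work to do.
- Visit-shift and per-treatment abundance effects (log-scale shifts on
  disjoint metabolite sets) give the visit-change and treatment scans
  true positives to find; the ground truth records every set.

What the generator does not emulate: inter-metabolite correlation
(pathway co-regulation), batch/run-day effects, joint-count components
of DAS28-CRP, and assay saturation. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
stated generative model, not performance on any real cohort.

## Calibration findings

Under the null generator (no causal, visit or treatment effects) the
Satterthwaite LMM scans run at the nominal 5% false-positive rate
(DAS28 scan ~4.9%, visit-change scan ~4.9% over 20 seeds x 686
metabolites). Two scans are measurably conservative and the acceptance
suite records this honestly rather than masking it:

- the logistic group scan (~2.8%): Wald z p-values without df
  correction are conservative when the random-intercept structure is
  strong and the number of patients moderate; the implementation agrees
  with `glmer` to 0.1%, so this is a property of the method, not of the
  code;
- the treatment scan (~4.3%): a Gaussian LMM applied to heavy-tailed
  log-normal abundance responses, as the analysis prescribes, is mildly
  conservative at this sample size.

## Problem sizes in the test suite

Unit tests run on reduced cohorts (16-40 patients, 25-80 metabolites)
that preserve the full statistical structure; the acceptance checks use
the default 64 x 2 + 12 cohort with 686 metabolites for calibration and
cross-validation (20 seeds) and 200 reduced replicates (24 patients, 60
metabolites, 3 causal) for CI coverage. These sizes were chosen so the
whole suite completes in minutes while keeping every Monte-Carlo band
meaningful.

## Known limitations

- Only a single random intercept is supported (no random slopes or
  crossed effects, no Kenward-Roger df).
- The logistic scan's Wald inference is conservative in small cohorts
  (see above); a likelihood-ratio or parametric-bootstrap option would
  calibrate better but would depart from the analysis being
  implemented.
- Minimum-value imputation biases low-abundance metabolites toward
  their detection limit; coverage experiments disable missingness for
  that reason.
- Continuous covariates are used in raw units (no standardization), so
  coefficient magnitudes depend on covariate scales.
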