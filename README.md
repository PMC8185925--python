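# rametab

Metabolome-wide association and prediction of rheumatoid-arthritis (RA)
disease activity from plasma metabolomics.

RA disease activity is routinely quantified with DAS28-CRP, a composite
score over 28 joints incorporating C-reactive protein (CRP). `rametab`
implements a complete, tested analysis pipeline that relates an
untargeted plasma metabolome (a samples × metabolites table of
"scaled imputed" intensities) to DAS28-CRP in a longitudinal cohort
where each patient contributes repeated visits:

- **Preprocessing** — per-metabolite median scaling to 1, removal of
  metabolites missing in >20% of samples, minimum-value imputation of
  the remaining (detection-limit) missing cells.
- **Mixed-effects scans** — for every metabolite, a linear mixed model
  `DAS28-CRP ~ metabolite + age + sex + (1 | patient)` fit by REML with
  Satterthwaite degrees of freedom for the metabolite coefficient, and a
  random-intercept logistic model of the dichotomized activity group
  (lower: DAS28-CRP ≤ 3.2; higher: > 3.2) fit by Laplace approximation
  with Wald z inference. Both engines are implemented in this package and
  validated against lmerTest / lme4 reference fits.
- **Prediction** — a Gaussian identity-link GLM of DAS28-CRP on the
  selected metabolites, evaluated by a patient-grouped leave-one-out
  cross-validation in which feature selection is re-run inside every
  fold on the training patients only (no leakage), and on an independent
  single-visit validation cohort. Without selection the model is the
  deterministic minimum-norm least-squares fit over all metabolites.
- **Secondary analyses** — hypergeometric pathway enrichment of the hit
  set, Fisher/McNemar/Wilcoxon confounder screens, per-treatment
  abundance associations, a two-stage covariate-screened comparison of
  CRP groups (high: CRP > 3.0 mg/L), and EULAR-response
  (good/moderate/none) visit-change scans.
- **Synthetic cohorts** — a first-class generator of discovery +
  validation cohorts with patient random intercepts, sparse causal
  metabolite effects, CRP coupled to DAS28-CRP, treatment/visit effects
  and left-censored missingness, with the ground truth returned for
  recovery tests.

The statistical model at the core is the random-intercept LMM

```
y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)
```

with patient i and visit j; the per-coefficient t statistic receives
Satterthwaite effective degrees of freedom
`nu = 2 Var(c'beta)^2 / (g' I^-1 g)` where `g` is the gradient of
`Var(c'beta)` in the variance components and `I` the observed REML
information. See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

```python
from rametab import (SimulationConfig, simulate_cohort, preprocess,
                     das28_association_scan, grouped_loocv)

abundance, meta, annotation, truth = simulate_cohort(SimulationConfig(seed=1))
processed, removed = preprocess(abundance)          # scale, filter, impute
disc = meta["cohort"] == "discovery"

scan, features = das28_association_scan(processed[disc], meta[disc])
print(len(features.metabolite_ids))                  # 50 metabolites, p < 0.05

with_sel, _ = grouped_loocv(processed[disc], meta[disc], with_selection=True)
without, _ = grouped_loocv(processed[disc], meta[disc], with_selection=False)
print(round(with_sel.mae, 2), round(without.mae, 2))  # 1.31 1.56
```

On this seed the scan keeps 50 of 686 metabolites at p < 0.05 and the
cross-validated mean absolute error of the GLM with nested feature
selection (1.31 DAS28-CRP units) beats the all-metabolite minimum-norm
baseline (1.56): selecting a sparse informative panel generalizes to
held-out patients, while the unselected interpolator overfits.

The same stages are exposed as a CLI
(`rametab simulate|preprocess|scan-groups|scan-das28|predict-cv|predict-validation|scan-treatment|scan-crp|scan-improvement|run-all`);
`run-all` executes everything from a YAML config and writes a manifest
whose checksums are byte-identical across reruns with the same seed.

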