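# Methods

This note documents the statistical model behind the package, the defaults
and why they were chosen, what the synthetic-trial generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## 1. The screening model

### Per-gene survival screen

Each gene is tested with a univariate Cox proportional-hazards model on
expression standardized over the analysis samples, so hazard ratios are per
SD of expression and comparable across genes. Wald p-values are used; ties
are handled with the Efron approximation throughout (both in the batch
primitives and in the lifelines-backed user-facing fits). A gene passes the
screen only if p < α for **both** DFS and OS in the training split
(α = 0.05, raw — no multiplicity correction is applied in the screens; the
screen is a filter, not an inference, and its false-positive rate is itself
tested). Fits that fail — constant expression, separation, fewer than two
distinct event times — are flagged and treated as non-significant so batch
screening is total.

The batch screens run on a vectorized single-covariate Newton–Raphson Cox
implementation and a vectorized two-group log-rank statistic (module
`_batchsurv`), which agree with lifelines to ~1e-6 (asserted in the test
suite) and make a 2,000-gene dual-endpoint screen a sub-second operation.

### Interaction screen

For each screen survivor the training samples are dichotomized at the
gene's **training-set mean** expression (the cutoff is frozen with the
gene record and never recomputed on validation data). Within each arm
separately a Mantel–Cox log-rank test and a high-vs-low Cox HR are
computed on DFS. A gene is an interaction (predictive) candidate when
exactly one arm is significant at α: genes significant in both arms behave
prognostically and are excluded; the arm identity is retained in the
output. Direction comes from the significant arm's HR — HR < 1 protective,
HR > 1 risk; an exact HR of 1 (measure zero) goes to the risk side with a
warning. Under the global null the expected selection rate is
2α(1−α) ≈ 0.095, which the acceptance suite verifies to Monte-Carlo
precision.

Where the Cox fit separates (small strata with complete separation) the
capped coefficient still carries the correct sign, so direction assignment
remains defined even when the magnitude is not estimable.

### MAD filter

Genes are removed when their MAD lies strictly below the
(1 − keep_fraction) quantile of all per-gene MADs (linear-interpolation
quantile; default keep_fraction 0.5 = strictly-below-median). On an
odd-length matrix with distinct MADs this removes exactly (n−1)/2 genes —
24,443 → 12,221 removed. Ties at the threshold are kept (strict
inequality) and reported by a warning rather than broken arbitrarily.

### Cohort split

The training/validation split (default ratio 0.65) is stratified by
arm × DFS-event by default so event rates and arm balance carry into both
halves; per-stratum training counts are `round(ratio·n)`, keeping every
stratum within one sample of the ratio. Strata smaller than two samples go
wholly to training with a warning. The split is a pure function of
(sample ids, ratio, seed, strata).

## 2. The forest score

A random survival forest (scikit-survival) is fit on DFS of the
**immunotherapy-arm** training patients with the marker genes as features:
the score is meant to rank outcomes *under treatment*, and including the
observation arm would re-blend prognostic signal the interaction screen
just removed. Defaults: 1,000 trees, √p features per split, minimum
terminal node size 15, fixed seed; all exposed in the config.

A sample's UAIscore is the forest-predicted survival probability at a
fixed **landmark time** (default: median observed follow-up of the fitting
samples; landmarks beyond the last observed time are clipped with a
warning). Orientation is therefore "higher = better predicted outcome under
immunotherapy" by construction, with no post-hoc sign flip. The
stratification cutoff is the **median score of all training patients (both
arms)** — the population in which the stratification is applied — and is
frozen in the model; validation scoring never recomputes it. An
alternative learner (e.g. classification-at-landmark) can be swapped in
behind the same contract (marker list + cutoff + landmark + orientation).

## 3. Evaluation layer

Kaplan–Meier, log-rank (Mantel–Cox, k groups) and multivariable Cox go
through lifelines. Constant covariates raise; rank-deficient designs and
non-convergence return a *flagged* result carrying diagnostics instead of
crashing, so batch callers stay total.

**Time-dependent AUC.** The cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights: cases at horizon t are
events with T ≤ t weighted by 1/G(T⁻), where G is the Kaplan–Meier
estimate of the censoring survival; controls are samples with T > t,
unweighted; tied scores count ½. The estimator is rank-based (invariant to
strictly monotone score transforms) and matches both a brute-force pair
enumeration and scikit-survival's implementation exactly in the tests.
Confidence bands are percentile bootstrap over samples (default 200
replicates); an analytic variance is deliberately not offered — the
bootstrap covers the estimator's full plug-in pipeline including G.
Evaluation times beyond observed follow-up are dropped with a warning.

**Multimodal combination.** Score and binary biomarkers are combined as
the linear predictor of a multivariable Cox model fit on training samples
with all components observed (complete-case per combination, with the
complete-case n reported); coefficients are frozen for scoring other
samples. The combined value is oriented as risk (higher = worse); its
negation is exposed for consistency with the benefit-oriented score.

**Benefit analysis.** Within each score stratum: Cox HR and log-rank p of
IO vs Obs; and the converse (score-group effect within each arm). A
stratum missing an arm is skipped with a warning rather than an error.

## 4. The synthetic-trial generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Expression**: marginally standard-normal log-scale values per gene,
  plus measurement noise (`noise_sd`, default 0.3). Planted classes form
  **co-expression modules**: genes in a class load on a shared factor with
  pairwise correlation `module_correlation` (default 0.9). The hazard acts
  through the standardized module mean, so each planted gene's marginal
  per-SD log-hazard is ≈ its class β (exactly β for a one-gene class)
  while total hazard heterogeneity stays bounded regardless of how many
  genes are planted — the behaviour of a real co-expressed signature, and
  the regime in which per-gene screens have interpretable power. Half the
  null genes (by default) are generated at a shrunken scale
  (`low_variation_scale` 0.25) to give the MAD filter the low-variation
  stratum it exists to remove.
- **Outcomes**: exponential baseline DFS hazard
  h·exp(β_prog·S_prog + arm·(β_risk·S_risk − β_prot·S_prot) + Σ β_b z_b),
  chosen exponential so censoring fractions and hazard ratios are
  analytically checkable. Censoring = min(exponential dropout,
  administrative horizon). OS is the latent DFS event time plus an
  exponential lag with rate `os_coupling` (larger = OS hugs DFS more
  tightly), censored by the same mechanisms — hence OS ≥ DFS sample by
  sample, as when death is a DFS event.
- **Biomarkers**: Bernoulli positives at configured prevalence, linked to
  the hazard through per-biomarker log-HRs; an optional knob correlates
  positivity with the latent benefit score. Post-treatment ctDNA is
  derived from baseline by a clearance probability and does not enter the
  hazard.
- **Truth**: per-gene class and coefficient, the per-sample latent benefit
  score (the negated predictive hazard component — what a perfect
  predictive biomarker would measure), and the true per-arm linear
  predictors used as oracle references in tests.

Defaults (the study conditions of all shipped tests): 728 patients,
1:1 arms, 2,000 genes with 30 prognostic (β = 0.5) and 30 + 30 predictive
(|β| = 1.0) genes, baseline hazard 0.05/month, administrative censoring at
36 months, dropout 0.01/month — giving ≈ 70 % DFS events; ctDNA positivity
35 % with log-HR 0.7, tTMB/PD-L1 modest protective effects. Effect sizes
are **illustrative**: the trial this emulates publishes no per-gene effect
magnitudes, so the defaults were chosen once as a plausibly strong
predictive signature and are not calibrated to any real cohort.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: count-level RNA-seq noise and library-size
effects, batch structure, non-proportional hazards, correlated
null-gene co-expression, informative censoring, biomarker measurement
error, or the (unknown) real effect-size distribution. Recovery rates here
certify the *procedure*, not expected yield on a given cohort.

## 5. Numerical decisions

- Batch Cox: Newton–Raphson with step clipping at |β| ≤ 20; hitting the
  cap flags separation (p forced to 1, sign retained). Convergence at
  |Δβ| < 1e-9, max 30 iterations.
- Degenerate survival inputs (no events, a single distinct event time,
  constant covariate) are flagged per gene, never raised, inside batch
  screens; user-facing fits raise with named offenders.
- Seed fan-out: the pipeline's global seed derives per-stage seeds via
  `SeedSequence([seed, stage_index])` mod 2³¹, so stages are independently
  rerunnable and all randomness is reproducible from one integer.
- Problem sizes in the shipped tests and the acceptance script (2,000-gene
  null calibrations, 150-gene × 20-seed recovery runs, 5–10 full pipeline
  replicates at 300 trees) were chosen as the smallest sizes at which the
  Monte-Carlo bounds in use are meaningful; all scale up by config.

## 6. Known limitations

- The interaction screen's arm-specific tests are marginal; it does not
  fit an explicit gene × arm interaction term, so its selection rate under
  unequal arm sizes is asymmetric in power, not in level.
- The forest's landmark-probability score discards post-landmark ranking
  information; concordance-oriented targets could do better late.
- The Cox combination of modalities assumes proportional hazards for each
  component; a logistic-at-landmark alternative is provided by
  configuration for settings where that is implausible.
- Bootstrap AUC bands are percentile-based and can be narrow at horizons
  with few comparable pairs.
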