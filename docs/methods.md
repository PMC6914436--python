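# Methods

This note documents the models, conventions and numerical choices behind
`pediclock`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The age transform

Children's blood methylomes change fastest in infancy and progressively more
slowly toward adolescence. The clock therefore regresses not age but a
transformed age `F(age)` that is logarithmic up to a knot `T` ("toddler
age", default 48 months) and linear beyond it:

```
F(a) = log(a + 1) − log(T + 1)   a ≤ T
F(a) = (a − T) / (T + 1)         a >  T
```

Both branches vanish at `a = T`; the derivative is `1/(a+1)` on the left and
`1/(T+1)` on the right, so `F` is C¹ as well as strictly increasing. The
inverse used for prediction is `(T+1)·eᵗ − 1` for `t ≤ 0` and `T + t(T+1)`
for `t > 0`; this algebraic form (rather than `exp(t + log(T+1)) − 1`) keeps
`F⁻¹(0) = T` exact in floating point, and the round-trip `F⁻¹∘F` is accurate
to better than 1e-9 months across (0, 228] months (checked on a dense grid).
Ages must exceed −1 month for the log branch; ages recorded in years are
converted by ×12 before any computation. Predictions are floored at 0.1
months so downstream ratios (AMAR) are always defined.

## Screening and the elastic net

With ~20k probes and a few hundred samples, the fit is preceded by sure
independence screening: probes are ranked by the absolute Pearson
correlation of their β values with `F(age)` and the top `⌊n / log n⌋` are
retained (the screening literature's usual default; configurable).
Zero-variance probes receive correlation 0 and can never outrank an
informative probe; rank ties break lexicographically by probe id so results
are deterministic.

The clock minimizes

```
(1/2n) Σ (F(ageᵢ) − β₀ − xᵢᵀβ)² + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²)
```

with mixing α = 0.48 by default. Conventions, chosen to match standard
`glmnet`-style practice:

* Predictors are standardized internally (population SD); reported
  coefficients are back-transformed to the raw β scale, so the penalty acts
  on the standardized scale. Columns with SD ≤ 1e-10 are treated as
  constant and excluded from scaling — without this guard, probes that are
  constant up to floating-point rounding (SD ~1e-18) make the raw-scale
  back-transform numerically explode.
* `λ = "cv"` selects the penalty minimizing mean squared CV error in
  transformed-age units over a 60-point log grid from `λ_max` (the smallest
  penalty with an empty model) down to `λ_max·1e-4`, with warm-started
  coordinate descent along the path. Human-facing accuracy is reported as
  the median absolute error in months of the held-out predictions, plus
  their pooled Pearson correlation with true age.
* The reported model is refit on all training samples at the chosen λ —
  k-fold splitting serves estimation of generalization error and penalty
  choice, not model averaging.
* `λ = 0` falls back to minimum-norm least squares, which interpolates when
  the effective predictor rank reaches the sample count and equals OLS when
  `n ≫ p`. `cv_folds=0` skips cross-validation entirely for training-set
  diagnostics at a fixed penalty.
* At convergence the coordinate-wise KKT conditions of the penalized
  objective hold to 1e-6 (asserted in the tests).

The published penalty λ = 0.000954 is kept as the documented default of
`ClockModel` for provenance, but fresh fits normally re-select λ by CV.

## Preprocessing chain

Order: missingness filter → kNN imputation → normalization → outlier
removal. The chain never reorders probes and never emits β outside [0, 1].

**Missingness filter.** Probes with more than `max_missing` (default 10)
missing values across all samples are dropped.

**kNN imputation** (k = 10 nearest *probes*). Distance between probes is
the root mean squared difference over samples where both are observed —
normalizing by the shared count keeps sparse overlaps comparable with dense
ones. Neighbors must be observed at the target sample; ties in distance
break by probe order; a probe with no usable neighbor falls back to its own
observed mean; imputed values are clipped to [0, 1]. Probes with fewer than
two observations are rejected by name.

**Normalization to a gold standard.** The reference is the per-probe mean β
of the largest (or designated) dataset. Two modes:

* `quantile`: rank-based mapping of each sample onto the reference
  distribution; exact when lengths match (sorted output equals sorted
  reference), interpolated on plotting positions otherwise. This is the
  default in the pipeline: it is monotone, fast and assumption-free.
* `bmiq`: a reference-matching adaptation of beta-mixture quantile
  normalization. A three-state beta mixture (unmethylated / hemimethylated
  / methylated) is fit by EM to the reference and to each sample; states
  are matched by ascending component mean, and each value moves through its
  state's beta CDF to the matched reference component's quantile. Original
  BMIQ corrects Infinium type-II against type-I probes within an array;
  here the same machinery aligns whole samples to a cross-dataset
  reference. Degenerate fits (e.g. near-constant samples) fall back to
  quantile mapping.

The EM uses method-of-moments initialization on value tertiles (hence fully
deterministic), an exact weighted-likelihood M-step (L-BFGS on log-shape
parameters via the beta sufficient statistics), tolerance 1e-4 on the
log-likelihood, and at most 200 iterations; the exact M-step guarantees a
monotone non-decreasing likelihood trace. Non-convergence sets a flag
rather than raising. Values at exactly 0/1 are nudged inward by 1e-6.
Heavy atoms at the boundaries can still drag the mixture into poor local
optima — one reason `quantile` is the default mode.

**Iterative PC1 outlier removal.** Per iteration: center probes, compute
each sample's PC1 score (via the top eigenpair of the sample Gram matrix —
deterministic, no randomized SVD), square its distance from the mean score,
z-score those squared distances, convert to one-sided upper-tail Gaussian
p-values, Benjamini–Hochberg adjust, and remove samples with adjusted value
strictly below the FDR threshold (default 0.2). Iterate until nothing is
removed or 20 rounds. *Known limitation:* squared PC1 distances are
χ²₁-like, much heavier-tailed than the Gaussian reference implied by the
z-score, so on data with little real structure the screen is aggressive —
on pure-noise matrices it can flag a large fraction of samples. On cohorts
whose PC1 carries real (age) signal it removes few samples and reliably
catches genuinely shifted ones: a sample displaced by ten probe-SDs is
flagged in the first iteration in 100/100 seeded runs (asserted by the
acceptance checks). Treat the per-iteration report as something to read,
not only a side effect.

BH adjustment itself is delegated to `statsmodels` and cross-checked in the
tests against a naive O(m²) step-up implementation.

## Synthetic cohorts

The generator emulates the structure of a merged 27K/450K pediatric blood
compendium so that every pipeline stage has a measurable ground truth:

* ages uniform on a range (default 9–212 months — the span of the public
  cohorts this mimics);
* a minority of "clock" probes (default 100 of 2,000) follow logistic
  trajectories `expit(b0 + b1·F(age))` with baseline logits in (−1.5, 1.5),
  slope magnitudes in [`effect_scale`, 2·`effect_scale`] (default 0.5 per
  unit transformed age) and exactly balanced signs; an optional fraction
  gains a quadratic term to produce the non-monotone, U-shaped trajectories
  seen at some CpGs; all other probes are age-independent;
* a `link="linear"` variant makes trajectories exactly affine in `F`
  (slopes clamped so they never clip at the [0, 1] boundary). This is the
  regime in which a linear clock with λ = 0 must reproduce training ages to
  numerical precision, and is what the exact-recovery check uses — a linear
  model cannot represent logistic trajectories exactly, so no such check is
  possible (or meaningful) under the logistic link;
* truncated Gaussian β noise (default SD 0.02 — a plausible array-scale
  technical noise level; the public data do not pin this down, so it is a
  package choice), random missingness (default 1%) that never leaves a
  sample with fewer than two observed probes, optional globally shifted
  outlier samples, monozygotic-twin pairs sharing age and clock-probe
  means, and group-level age-acceleration shifts implemented as effective
  age offsets on clock probes only;
* one RNG stream per component (ages, coefficients, noise, masking,
  outliers, grouping), split from a single seed, so toggling one feature
  does not perturb the draws of the others; identical specs are bitwise
  reproducible.

What it does **not** emulate: probe-type chemistry, cell-composition
heterogeneity, batch structure, age-dependent noise, or realistic
probe-probe correlation beyond the shared age signal. Passing recovery
checks therefore demonstrate correctness of the estimation machinery, not
performance on real arrays.

Sizes used by the standing checks (a balance of resolution against desk-run
time): recovery on 500 samples × 2,000 probes with 100 clock probes and
noise SD 0.02; oracle comparisons on 20 × 10 instances; outlier detection on
300 × 100 matrices over 100 seeds; calibration with 10⁴ null replicates and
10⁵ power replicates.

## Acceleration statistics

AAD = DNAm age − age (months); AMAR = DNAm age / age. Childhood periods are
half-open bins on months — toddlerhood [0, 60), mid-childhood [60, 144),
adolescence from 144 — fixing a deterministic convention for the year-level
boundaries (0–4, 5–11, 12–18).

Group comparisons follow the layout of published case/control acceleration
tables:

* Δmean with Welch standard error `√(s₁²/n₁ + s₂²/n₂)`; p-value from
  Welch's t with Satterthwaite degrees of freedom.
* Cohen's d with the (n−2)-weighted pooled SD and
  `SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`.
* 95% CIs use a fixed 1.96 normal multiplier by default — this is the
  convention that reproduces the published intervals exactly; a t-quantile
  variant is available by flag.
* Power is post hoc under the noncentral t with noncentrality
  `d·√(n₁n₂/(n₁+n₂))` and df `n₁+n₂−2`, i.e. the pooled two-sample t-test.
  A Monte Carlo of that pooled test agrees with the formula to within
  simulation error; a Monte Carlo of *Welch's* test at small unbalanced n
  (13 vs 7) runs ~0.02–0.03 lower, since Welch's random Satterthwaite df
  cost power there. The published power percentages match neither
  convention exactly and are not treated as reproducible targets. scipy's
  noncentral-t tail can lose mass at large noncentrality; the
  implementation falls back to the (there exact-to-double) normal
  approximation when that happens.
* Paired comparisons return the paired t plus the mean |difference| (the
  twin-discordance statistic); a constant nonzero shift with zero
  difference-variance reports t = ±∞ and p = 0 rather than NaN.
* One-way fixed-effects ANOVA (scipy) with an all-equal guard (F = 0,
  p = 1); the Wilcoxon rank-sum uses exact enumeration when both groups
  have n ≤ 10 without ties, otherwise the tie-corrected normal
  approximation.
* `generate_group_summaries` reconstructs Gaussian raw samples whose
  empirical mean and ddof-1 SD match published summary cells exactly, so
  summary-form and raw-form analyses can be cross-checked.

## Design choices that were genuinely open

* **Probe order** after cross-platform merging is lexicographic, samples in
  input order: deterministic outputs over faithfulness to any particular
  upstream file order.
* **Outlier z-score** is computed on the squared PC1 distance directly (no
  log transform), one-sided upper tail — the most literal reading of
  "squared distance converted to a z-score", with the heavy-tail caveat
  above.
* **"FDR < 0.2"** is a strict inequality on BH-adjusted values.
* **NA tokens** in delimited input: empty string, `NA`, `NaN`
  (case-insensitive), matching common series-matrix exports; `#`-prefixed
  lines are provenance comments.
* **Model files** are versioned JSON with a closed key set; unknown or
  missing keys are format errors, and floats round-trip losslessly.
* **CLI provenance**: every output carries the package version and a hash
  of the effective configuration (no timestamps), so identical runs are
  byte-identical; files are written via temp-file-and-rename so partial
  outputs never appear.

## Known limitations

* The published 111-CpG coefficient set is not reproduced — that requires
  the original GEO training cohorts; synthetic parameter recovery stands in
  for it.
* The BMIQ-style mode is a reference-matching adaptation, not the original
  within-array type-I/type-II correction; it can be distorted by heavy
  atoms at β = 0/1.
* The PC1 outlier screen over-flags unstructured data (see above).
* No cell-type deconvolution, batch correction, or covariate-adjusted
  acceleration models; comparisons are the plain one-way analyses of the
  published tables.
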