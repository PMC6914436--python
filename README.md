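# pediclock

A child-specific DNA methylation age clock, packaged as a tested Python
library and command-line pipeline.

Epigenetic clocks predict chronological age from DNA methylation β values
(the per-CpG fraction methylated, in [0, 1]) and use the residual "age
acceleration" as a biomarker of health. Most published clocks are trained on
adults and lose precision exactly where methylation changes fastest: the
first two decades of life. `pediclock` implements a pediatric clock for ages
0–18 years (in months) of the kind trained on merged Illumina 27K/450K blood
cohorts, together with everything needed to exercise it end to end without
external data:

* **I/O** for probes × samples β matrices (CSV/TSV), sample metadata, probe
  annotation, and versioned JSON clock models; cross-platform probe
  intersection that drops sex-chromosome markers.
* **Preprocessing**: missingness filtering (≤ 10 missing values per probe),
  k-nearest-probe imputation (k = 10), normalization of every sample toward
  a gold-standard reference distribution (three-state beta-mixture quantile
  mapping in the spirit of BMIQ, or plain quantile mapping), and iterative
  PCA-based outlier removal at an FDR threshold of 0.2.
* **The clock**: sure independence screening followed by an elastic-net fit
  (α = 0.48) on a transformed age scale, with 10-fold cross-validation for
  the penalty strength.
* **Acceleration statistics**: AAD and AMAR, childhood-period
  stratification, and the Welch/Cohen's-d/power machinery used to compare
  groups (autism vs. unaffected siblings, lead-exposed vs. non-exposed, twin
  discordance).
* **A synthetic-cohort generator** with known ground-truth clock structure,
  so the full train→predict loop is testable and its parameter recovery
  measurable.

## The model

Age in months is mapped through a piecewise transform `F` with a knot at the
"toddler age" `T = 48` months:

```
F(age) = log(age + 1) − log(T + 1)    if age ≤ T
F(age) = (age − T) / (T + 1)          if age > T
```

`F` is continuous and strictly increasing, logarithmic where methylation
turns over fastest (infancy/toddlerhood) and linear afterwards. The clock is
an elastic net on β values predicting `F(age)`:

```
min over (β₀, β):  (1/2n) Σᵢ (F(ageᵢ) − β₀ − xᵢᵀβ)² + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²)
```

with predictors standardized internally and coefficients reported on the raw
β scale. The DNA methylation age (DNAm age) of a sample is
`F⁻¹(β₀ + xᵀβ)`. Two per-sample acceleration measures follow:

* **AAD** (age acceleration difference) = DNAm age − age, in months;
* **AMAR** (apparent methylation aging rate) = DNAm age / age.

Because `p ≫ n`, probes are first ranked by |Pearson r| between β and
`F(age)` (sure independence screening) and the top `⌊n / log n⌋` enter the
penalized fit.

See `docs/methods.md` for assumptions, parameter conventions, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from pediclock import (CohortSpec, generate_cohort, filter_probes_by_missingness,
                       knn_impute, bmiq_normalize, NormalizationReference,
                       pca_outlier_filter, sis_screen, fit_clock, TransformParams,
                       predict_dnam_age, compute_acceleration, anova_compare)

spec = CohortSpec(n_samples=300, n_probes=1000, n_clock_probes=60, seed=42)
beta, metadata, truth = generate_cohort(spec)

m = filter_probes_by_missingness(beta, max_missing=10)
m = knn_impute(m, k=10)
m = bmiq_normalize(m, NormalizationReference.from_matrix(m), mode="quantile")
m, qc = pca_outlier_filter(m, fdr_threshold=0.2)

ages = metadata.set_index("sample_id").loc[m.sample_ids, "age_months"].to_numpy()
probes = sis_screen(m, ages, TransformParams(), n_keep="auto")
model, cv = fit_clock(m.subset_probes(probes), ages, lam="cv", cv_folds=10, seed=0)
print(f"outliers removed: {qc.total_removed}")
print(f"probes screened in: {len(probes)}, non-zero coefficients: "
      f"{model.training_summary['n_nonzero']}")
print(f"held-out r = {cv.pooled_correlation:.3f}, "
      f"median |error| = {cv.pooled_median_abs_error:.2f} months")

table = compute_acceleration(
    dict(zip(m.sample_ids, predict_dnam_age(model, m))),
    metadata[metadata.sample_id.isin(m.sample_ids)],
)
res = anova_compare([g["aad"].to_numpy() for _, g in table.groupby("period")])
print(f"AAD across childhood periods: F = {res.f_statistic:.2f}, "
      f"p = {res.p_value:.3g}")
```

Output:

```
outliers removed: 97
probes screened in: 38, non-zero coefficients: 32
held-out r = 0.998, median |error| = 1.23 months
AAD across childhood periods: F = 1.31, p = 0.253
```

Reading it: on a 300-sample synthetic cohort with 60 age-responsive probes,
the cross-validated clock predicts held-out ages with r = 0.998 and a median
absolute error of 1.2 months. The PC1 outlier screen is deliberately
aggressive on low-structure data (see the methods note). The period ANOVA is
correctly null — this generator run planted no period-dependent
acceleration, so AAD does not differ between toddlerhood, mid-childhood and
adolescence.

The same pipeline is available from the shell:

```sh
pediclock simulate --n-samples 300 --n-probes 1000 --n-clock-probes 60 \
    --seed 42 --out-dir cohort/
pediclock preprocess --beta cohort/beta.tsv --out cohort/clean.tsv
pediclock train --beta cohort/clean.tsv --metadata cohort/metadata.csv \
    --model-out cohort/model.json --cv-report cohort/cv.json
pediclock predict --model cohort/model.json --beta cohort/clean.tsv \
    --out cohort/predictions.csv
pediclock accelerate --model cohort/model.json --beta cohort/clean.tsv \
    --metadata cohort/metadata.csv --out cohort/acceleration.csv
pediclock compare --table cohort/acceleration.csv --group-col period \
    --measure aad --test anova --out cohort/comparison.json
```

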