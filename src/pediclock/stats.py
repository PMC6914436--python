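"""Age-acceleration measures and group-comparison statistics.

Two per-sample acceleration measures derive from a clock prediction:

* AAD (age acceleration difference) = DNAm age - chronological age, months;
* AMAR (apparent methylation aging rate) = DNAm age / chronological age.

Childhood is stratified into toddlerhood ([0, 60) months), mid-childhood
([60, 144)) and adolescence (144 months and up).  Group contrasts report the
mean difference with its Welch standard error, pooled-SD Cohen's d with a
normal-approximation confidence interval, a p-value, and post-hoc power
under the noncentral t distribution — the summary layout used in cohort
tables of case/control acceleration differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "GroupComparison",
    "PairedComparison",
    "AnovaResult",
    "assign_period",
    "compute_acceleration",
    "cohens_d",
    "welch_compare",
    "ttest_power",
    "paired_compare",
    "anova_compare",
    "wilcoxon_compare",
]

PERIODS = ("toddlerhood", "mid_childhood", "adolescence")
TODDLER_UPPER_MONTHS = 60.0
MID_CHILDHOOD_UPPER_MONTHS = 144.0


def assign_period(age_months: float) -> str:
    """Childhood period for an age in months (half-open bins at 60 and 144)."""
    if age_months < 0:
        raise ValidationError("age must be non-negative")
    if age_months < TODDLER_UPPER_MONTHS:
        return "toddlerhood"
    if age_months < MID_CHILDHOOD_UPPER_MONTHS:
        return "mid_childhood"
    return "adolescence"


def compute_acceleration(predictions, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample acceleration table (AAD, AMAR, childhood period).

    ``predictions`` maps sample id -> DNAm age in months (mapping or pandas
    Series); ``metadata`` must carry ``sample_id`` and positive
    ``age_months``.  Extra metadata columns (sex, group, ...) pass through.
    """
    pred = dict(predictions)
    missing = [s for s in metadata["sample_id"] if s not in pred]
    if missing:
        raise ValidationError(f"no prediction for samples {missing[:5]}")
    ages = metadata["age_months"].to_numpy(dtype=float)
    if (ages <= 0).any():
        raise ValidationError("age_months must be positive")
    dnam = np.array([pred[s] for s in metadata["sample_id"]], dtype=float)
    table = metadata.copy().reset_index(drop=True)
    table["dnam_age_months"] = dnam
    table["aad"] = dnam - ages
    table["amar"] = dnam / ages
    table["period"] = [assign_period(a) for a in ages]
    return table


# ---------------------------------------------------------------------------
# effect sizes and two-group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-group summary in the cohort-table layout."""

    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    delta_mean: float
    se_delta: float
    ci95_delta: tuple[float, float]
    cohens_d: float
    ci95_d: tuple[float, float]
    p_value: float
    power: float
    test: str


def _check_group(n: int, sd: float) -> None:
    if n < 2:
        raise ValidationError("group size must be >= 2")
    if sd <= 0:
        raise ValidationError("group sd must be positive")


def cohens_d(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
    z: float = 1.96,
) -> tuple[float, tuple[float, float]]:
    """Pooled-SD Cohen's d with a normal-approximation 95% CI.

    ``d = (mean1 - mean2) / s_pooled`` with the usual (n-2)-weighted pooled
    variance; ``SE(d) = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)))``.
    """
    _check_group(n1, sd1)
    _check_group(n2, sd2)
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / s_pooled
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return d, (d - z * se, d + z * se)


def welch_compare(
    sample1=None,
    sample2=None,
    *,
    summaries: tuple[float, ...] | None = None,
    z: float = 1.96,
    use_t_ci: bool = False,
    power_sides: str = "two",
) -> GroupComparison:
    """Welch two-sample comparison from raw samples or (n, mean, sd) summaries.

    ``se_delta = sqrt(sd1^2/n1 + sd2^2/n2)``; the 95% CI on the mean
    difference uses a 1.96 normal multiplier by default (``use_t_ci`` swaps
    in the Satterthwaite t quantile).  The p-value comes from Welch's t with
    Satterthwaite degrees of freedom; power is post hoc at the observed d.
    """
    if summaries is not None:
        n1, mean1, sd1, n2, mean2, sd2 = summaries
        n1, n2 = int(n1), int(n2)
    else:
        x1 = np.asarray(sample1, dtype=float)
        x2 = np.asarray(sample2, dtype=float)
        n1, n2 = x1.size, x2.size
        if n1 < 2 or n2 < 2:
            raise ValidationError("group size must be >= 2")
        mean1, mean2 = float(x1.mean()), float(x2.mean())
        sd1, sd2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    delta = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if delta == 0:
            d, ci_d = 0.0, (0.0, 0.0)
            return GroupComparison(
                n1, n2, mean1, sd1, mean2, sd2, 0.0, 0.0, (0.0, 0.0),
                d, ci_d, 1.0, math.nan, "welch_t",
            )
        raise ValidationError("degenerate groups with zero variance")
    _check_group(n1, max(sd1, 1e-300))
    _check_group(n2, max(sd2, 1e-300))
    se = math.sqrt(sd1**2 / n1 + sd2**2 / n2)
    df = se**4 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    t_stat = delta / se if se > 0 else math.inf * np.sign(delta)
    p = float(2 * sps.t.sf(abs(t_stat), df)) if math.isfinite(t_stat) else 0.0
    mult = float(sps.t.ppf(0.975, df)) if use_t_ci else z
    if sd1 > 0 and sd2 > 0:
        d, ci_d = cohens_d(n1, mean1, sd1, n2, mean2, sd2, z=z)
        power = ttest_power(d, n1, n2, sides=power_sides)
    else:
        d, ci_d, power = math.nan, (math.nan, math.nan), math.nan
    return GroupComparison(
        n1=n1, n2=n2, mean1=mean1, sd1=sd1, mean2=mean2, sd2=sd2,
        delta_mean=delta, se_delta=se,
        ci95_delta=(delta - mult * se, delta + mult * se),
        cohens_d=d, ci95_d=ci_d, p_value=min(p, 1.0), power=power,
        test="welch_t",
    )


def ttest_power(
    d: float, n1: int, n2: int, alpha: float = 0.05, sides: str = "two"
) -> float:
    """Power of a two-sample t-test at effect size d (noncentral t).

    Noncentrality ``d * sqrt(n1 n2 / (n1 + n2))``, ``df = n1 + n2 - 2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("group size must be >= 2")
    if not math.isfinite(d):
        raise ValidationError("effect size must be finite")
    if sides not in {"one", "two"}:
        raise ValidationError("sides must be 'one' or 'two'")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    def _upper(crit):
        v = float(sps.nct.sf(crit, df, ncp))
        # scipy's noncentral t can lose the extreme tail; fall back to the
        # normal approximation, which is exact to double precision there.
        return v if math.isfinite(v) else float(sps.norm.sf(crit - ncp))

    def _lower(crit):
        v = float(sps.nct.cdf(crit, df, ncp))
        return v if math.isfinite(v) else float(sps.norm.cdf(crit - ncp))

    if sides == "one":
        return _upper(sps.t.ppf(1 - alpha, df))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return min(1.0, _upper(crit) + _lower(-crit))


@dataclass
class PairedComparison:
    n_pairs: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    mean_abs_diff: float
    test: str = "paired_t"


def paired_compare(values1, values2) -> PairedComparison:
    """Paired t-test on per-pair differences, plus the mean |difference|
    (the discordance statistic used for monozygotic-twin validation)."""
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("paired samples must be equal-length vectors")
    if x1.size < 2:
        raise ValidationError("need at least 2 pairs")
    diff = x1 - x2
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0:
        if mean_diff == 0:
            return PairedComparison(x1.size, 0.0, 0.0, 0.0, 1.0, 0.0)
        # Constant nonzero shift: t is unbounded; report p below any threshold.
        return PairedComparison(
            x1.size, mean_diff, 0.0, math.inf * np.sign(mean_diff), 0.0,
            float(np.abs(diff).mean()),
        )
    t = mean_diff / (sd_diff / math.sqrt(x1.size))
    p = float(2 * sps.t.sf(abs(t), x1.size - 1))
    return PairedComparison(
        x1.size, mean_diff, sd_diff, float(t), p, float(np.abs(diff).mean())
    )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    test: str = "anova"


def anova_compare(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AnovaResult(0.0, 1.0, len(arrays) - 1, pooled.size - len(arrays))
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), len(arrays) - 1, pooled.size - len(arrays))


def wilcoxon_compare(sample1, sample2) -> tuple[float, float]:
    """Wilcoxon rank-sum test; exact null when both groups have n <= 10 and
    no ties, otherwise the tie-corrected normal approximation."""
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 1 or x2.size < 1:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x1.size <= 10 and x2.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
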