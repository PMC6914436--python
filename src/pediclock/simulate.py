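"""Synthetic pediatric methylation cohorts with known clock structure.

A cohort consists of a probes x samples beta matrix, per-sample metadata and
the generating ("ground truth") clock description.  A minority of probes —
the clock probes — follow logistic trajectories in transformed age,

    beta_j(age) = logistic(b0_j + b1_j * F(age))  [+ optional quadratic term],

with balanced positive and negative slopes; the remaining probes have
age-independent means.  Truncated Gaussian measurement noise, random
missingness, shifted outlier samples, twin pairs that share age and clock
trajectories, and group-level age-acceleration shifts emulate the structure
of merged public 27K/450K pediatric blood datasets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockModel, TransformParams, f_transform
from .io import BetaMatrix, ValidationError

__all__ = ["CohortSpec", "generate_cohort", "generate_group_summaries"]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mimic a mid-sized merged pediatric cohort: 500 blood samples
    aged 9-212 months on ~2,000 shared autosomal probes, of which 100 carry
    an age signal, with beta-scale noise of 0.02 and 1% missing entries.
    """

    n_samples: int = 500
    n_probes: int = 2000
    n_clock_probes: int = 100
    age_range_months: tuple[float, float] = (9.0, 212.0)
    toddler_age: float = 48.0
    effect_scale: float = 0.5  # minimum |logit slope| per unit transformed age
    noise_sd: float = 0.02
    missing_rate: float = 0.01
    n_outliers: int = 0
    outlier_shift_sd: float = 0.15
    group_effects: dict[str, float] = field(default_factory=dict)
    n_twin_pairs: int = 0
    quadratic_fraction: float = 0.0  # fraction of clock probes with a bend
    link: str = "logistic"  # "logistic" or "linear" beta trajectories
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_probes < 1:
            raise ValidationError("need at least one sample and one probe")
        if not 0 <= self.n_clock_probes <= self.n_probes:
            raise ValidationError("n_clock_probes must be in [0, n_probes]")
        lo, hi = self.age_range_months
        if not 0 < lo < hi:
            raise ValidationError("age range must satisfy 0 < low < high")
        if self.toddler_age <= 0:
            raise ValidationError("toddler_age must be positive")
        if self.effect_scale < 0 or self.noise_sd < 0 or self.outlier_shift_sd < 0:
            raise ValidationError("scales must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0 <= self.n_outliers < self.n_samples:
            raise ValidationError("n_outliers must be < n_samples")
        if not 0 <= self.quadratic_fraction <= 1:
            raise ValidationError("quadratic_fraction must be in [0, 1]")
        if 2 * self.n_twin_pairs > self.n_samples:
            raise ValidationError("too many twin pairs for n_samples")
        if self.link not in {"logistic", "linear"}:
            raise ValidationError("link must be 'logistic' or 'linear'")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, pd.DataFrame, ClockModel]:
    """Generate a cohort; identical specs produce bitwise-identical output.

    The RNG stream is split per component (ages, coefficients, noise,
    masking, outliers, grouping) so that toggling one feature leaves the
    others' draws unchanged.
    """
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_age, rng_coef, rng_noise, rng_mask, rng_out, rng_grp = (
        np.random.default_rng(s) for s in streams
    )
    n, p, pc = spec.n_samples, spec.n_probes, spec.n_clock_probes
    params = TransformParams(spec.toddler_age)

    probe_ids = [f"cg{i:08d}" for i in range(1, p + 1)]
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    lo, hi = spec.age_range_months
    ages = rng_age.uniform(lo, hi, size=n)
    # Twin pairs occupy the leading sample slots and share an age.
    for t in range(spec.n_twin_pairs):
        ages[2 * t + 1] = ages[2 * t]

    sexes = np.where(rng_grp.random(n) < 0.5, "M", "F")
    if spec.group_effects:
        labels = sorted(spec.group_effects)
        groups = np.array(labels)[rng_grp.integers(0, len(labels), size=n)]
        for t in range(spec.n_twin_pairs):
            groups[2 * t + 1] = groups[2 * t]
        shift = np.array([spec.group_effects[g] for g in groups])
    else:
        groups = np.array(["healthy"] * n)
        shift = np.zeros(n)

    # Generating parameters: clock probes get a baseline and a slope of
    # magnitude in [effect_scale, 2*effect_scale] with balanced signs.  With
    # the logistic link the slope acts on the logit scale; with the linear
    # link it is a beta-scale slope, clamped so trajectories never leave
    # (0, 1) over the age range (which would reintroduce nonlinearity).
    clock_idx = np.sort(rng_coef.choice(p, size=pc, replace=False))
    f_lo, f_hi = f_transform(np.array(spec.age_range_months), params)
    f_absmax = max(abs(f_lo), abs(f_hi))
    if spec.link == "logistic":
        b0 = rng_coef.uniform(-1.5, 1.5, size=pc)
        mags = rng_coef.uniform(spec.effect_scale, 2.0 * spec.effect_scale, size=pc)
    else:
        b0 = rng_coef.uniform(0.4, 0.6, size=pc)
        cap = 0.38 / f_absmax
        mags = rng_coef.uniform(
            min(spec.effect_scale, cap), min(2.0 * spec.effect_scale, cap), size=pc
        )
    signs = np.ones(pc)
    signs[1::2] = -1.0
    signs = rng_coef.permutation(signs)
    b1 = mags * signs
    b2 = np.zeros(pc)
    n_quad = int(round(spec.quadratic_fraction * pc))
    if n_quad:
        quad_idx = rng_coef.choice(pc, size=n_quad, replace=False)
        b2[quad_idx] = rng_coef.uniform(-0.5, 0.5, size=n_quad)
    flat_means = rng_coef.uniform(0.05, 0.95, size=p)

    # Group shifts act on the clock probes only, as an effective-age offset.
    eff_age = np.clip(ages + shift, 0.5, None)
    f_eff = f_transform(eff_age, params)
    means = np.tile(flat_means[:, None], (1, n))
    lin_pred = (
        b0[:, None] + b1[:, None] * f_eff[None, :] + b2[:, None] * f_eff[None, :] ** 2
    )
    means[clock_idx, :] = (
        _logistic(lin_pred) if spec.link == "logistic" else np.clip(lin_pred, 0.0, 1.0)
    )
    # Twins share clock-probe means exactly (same age, same group).
    for t in range(spec.n_twin_pairs):
        means[clock_idx, 2 * t + 1] = means[clock_idx, 2 * t]

    values = means.copy()
    if spec.noise_sd > 0:
        values = values + rng_noise.normal(0.0, spec.noise_sd, size=(p, n))
    if spec.n_outliers > 0:
        out_cols = rng_out.choice(n, size=spec.n_outliers, replace=False)
        values[:, out_cols] += rng_out.normal(
            0.0, spec.outlier_shift_sd, size=(p, spec.n_outliers)
        )
    np.clip(values, 0.0, 1.0, out=values)

    if spec.missing_rate > 0:
        mask = rng_mask.random((p, n)) < spec.missing_rate
        # Never let masking leave a sample with fewer than 2 observed probes.
        for j in range(n):
            col = mask[:, j]
            excess = p - int(col.sum())
            if excess < 2:
                unmask = np.where(col)[0][: 2 - excess]
                mask[unmask, j] = False
        values = values.copy()
        values[mask] = np.nan

    beta = BetaMatrix(probe_ids, sample_ids, values)
    twin_pair = [""] * n
    for t in range(spec.n_twin_pairs):
        twin_pair[2 * t] = twin_pair[2 * t + 1] = f"pair{t + 1:03d}"
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_months": ages,
            "sex": sexes,
            "group": groups,
            "dataset_id": ["synthetic"] * n,
            "twin_pair": twin_pair,
        }
    )

    clock_probes = [probe_ids[i] for i in clock_idx]
    truth = ClockModel(
        intercept=0.0,
        coefficients={probe_ids[i]: float(s) for i, s in zip(clock_idx, b1)},
        toddler_age=spec.toddler_age,
        alpha=0.48,
        lam=0.000954,
        training_summary={
            "kind": "generative",
            "clock_probes": clock_probes,
            "b0": {pid: float(v) for pid, v in zip(clock_probes, b0)},
            "b1": {pid: float(v) for pid, v in zip(clock_probes, b1)},
            "b2": {pid: float(v) for pid, v in zip(clock_probes, b2)},
            "spec": _spec_as_dict(spec),
        },
    )
    return beta, metadata, truth


def _spec_as_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["age_range_months"] = list(d["age_range_months"])
    return d


def generate_group_summaries(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian samples rescaled so empirical means/SDs match exactly.

    SDs are sample standard deviations (ddof=1), matching how cohort tables
    report Mean+/-SD.  Useful for reconstructing raw-data analyses from
    published summary rows.
    """
    rng = np.random.default_rng(seed)
    out = []
    for n, mean, sd in ((n1, mean1, sd1), (n2, mean2, sd2)):
        if int(n) != n or n < 2:
            raise ValidationError("group size must be an integer >= 2")
        if sd <= 0:
            raise ValidationError("sd must be positive")
        z = rng.standard_normal(int(n))
        while np.std(z, ddof=1) == 0:  # pragma: no cover - essentially impossible
            z = rng.standard_normal(int(n))
        out.append(mean + sd * (z - z.mean()) / np.std(z, ddof=1))
    return out[0], out[1]
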