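"""Quality control and normalization for cross-platform beta matrices.

The chain mirrors common practice for merged 27K/450K pediatric blood
cohorts: drop probes with too many missing values, impute the rest with a
k-nearest-probes rule, adjust every sample's beta distribution toward a
gold-standard reference (either a three-state beta-mixture quantile mapping
in the spirit of BMIQ, or plain rank-based quantile mapping), and finally
remove outlying samples by an iterative PC1-distance test controlled at an
FDR threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ValidationError

__all__ = [
    "NormalizationReference",
    "OutlierReport",
    "BetaMixtureResult",
    "filter_probes_by_missingness",
    "knn_impute",
    "fit_beta_mixture",
    "bmiq_normalize",
    "pca_outlier_filter",
    "bh_adjust",
]


@dataclass
class NormalizationReference:
    """Per-probe gold-standard beta values (typically means of the largest
    single dataset), defining the target distribution for normalization."""

    probe_ids: list[str]
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        if self.reference_values.shape != (len(self.probe_ids),):
            raise ValidationError("reference length mismatch")
        if np.isnan(self.reference_values).any():
            raise ValidationError("reference contains missing values")
        if self.reference_values.min() < 0 or self.reference_values.max() > 1:
            raise ValidationError("reference values outside [0, 1]")

    @classmethod
    def from_matrix(cls, m: BetaMatrix) -> "NormalizationReference":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(m.values, axis=1)
        if np.isnan(means).any():
            raise ValidationError("a probe has no observed values in the reference")
        return cls(list(m.probe_ids), means)

    def aligned_to(self, probe_ids: list[str]) -> np.ndarray:
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            rows = [idx[p] for p in probe_ids]
        except KeyError as exc:
            raise ValidationError(f"reference missing probe {exc.args[0]!r}") from exc
        return self.reference_values[rows]


@dataclass
class OutlierIteration:
    removed_sample_ids: list[str]
    z_scores: dict[str, float]
    fdr_values: dict[str, float]


@dataclass
class OutlierReport:
    iterations: list[OutlierIteration] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return sum(len(it.removed_sample_ids) for it in self.iterations)

    @property
    def removed_sample_ids(self) -> list[str]:
        out: list[str] = []
        for it in self.iterations:
            out.extend(it.removed_sample_ids)
        return out

    def to_dict(self) -> dict:
        return {
            "total_removed": self.total_removed,
            "iterations": [
                {
                    "removed_sample_ids": it.removed_sample_ids,
                    "z_scores": it.z_scores,
                    "fdr_values": it.fdr_values,
                }
                for it in self.iterations
            ],
        }


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------

def filter_probes_by_missingness(m: BetaMatrix, max_missing: int = 10) -> BetaMatrix:
    """Keep probes with at most ``max_missing`` missing values across samples."""
    counts = np.isnan(m.values).sum(axis=1)
    keep = [p for p, c in zip(m.probe_ids, counts) if c <= max_missing]
    return m.subset_probes(keep)


# ---------------------------------------------------------------------------
# kNN imputation over probes
# ---------------------------------------------------------------------------

def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute each missing entry from the k nearest probes.

    Distance between two probes is the root mean squared difference over the
    samples where both are observed (so sparser overlap is not penalized);
    the target sample never contributes, since the target probe is missing
    there.  Neighbors must be observed at the target sample; ties in distance
    break by probe order.  A probe with no usable neighbor falls back to its
    own observed mean.  Imputed values are clipped to [0, 1].
    """
    values = m.values.copy()
    obs = ~np.isnan(values)
    n_obs = obs.sum(axis=1)
    if (n_obs < 2).any():
        bad = m.probe_ids[int(np.argmax(n_obs < 2))]
        raise ValidationError(f"probe {bad!r} has fewer than 2 observed values")
    if obs.all():
        return m.copy()

    z = np.where(obs, values, 0.0)
    mask = obs.astype(float)
    # Sum of squared diffs over shared samples, via masked matrix products.
    zz = z @ z.T
    a = (z**2) @ mask.T
    shared = mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(a + a.T - 2.0 * zz, 0.0) / shared)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    probe_means = np.where(n_obs > 0, np.nansum(values, axis=1) / n_obs, np.nan)
    missing_rows = np.where(~obs.all(axis=1))[0]
    for i in missing_rows:
        order = np.lexsort((np.arange(m.n_probes), dist[i]))
        finite = order[np.isfinite(dist[i, order])]
        for j in np.where(~obs[i])[0]:
            cand = finite[obs[finite, j]][:k]
            if cand.size:
                values[i, j] = values[cand, j].mean()
            else:
                values[i, j] = probe_means[i]
    np.clip(values, 0.0, 1.0, out=values)
    return BetaMatrix(
        list(m.probe_ids), list(m.sample_ids), values, dict(m.platform_of_sample)
    )


# ---------------------------------------------------------------------------
# three-state beta mixture (EM)
# ---------------------------------------------------------------------------

@dataclass
class BetaMixtureResult:
    """Fitted beta mixture: shapes ``a``/``b`` and ``weights`` per component
    (sorted by ascending component mean), per-value responsibilities and hard
    state assignments, and the EM log-likelihood trace."""

    a: np.ndarray
    b: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    assignments: np.ndarray
    log_likelihood: list[float]
    converged: bool
    degenerate: bool = False

    @property
    def component_means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


_EPS = 1e-6


def _nudge(values: np.ndarray) -> np.ndarray:
    return np.clip(values, _EPS, 1.0 - _EPS)


def _mom_beta(x: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(x))
    var = float(np.var(x))
    var = max(var, 1e-6)
    common = max(mu * (1 - mu) / var - 1.0, 0.02)
    return max(mu * common, 0.01), max((1 - mu) * common, 0.01)


def _mle_beta(w: np.ndarray, logx: np.ndarray, log1mx: np.ndarray, a0: float, b0: float):
    """Weighted beta MLE via the exponential-family sufficient statistics."""
    wsum = float(w.sum())
    s1 = float(w @ logx)
    s2 = float(w @ log1mx)

    def neg(theta):
        a, b = np.exp(theta)
        val = wsum * special.betaln(a, b) - (a - 1) * s1 - (b - 1) * s2
        da = wsum * (special.digamma(a) - special.digamma(a + b)) - s1
        db = wsum * (special.digamma(b) - special.digamma(a + b)) - s2
        return val, np.array([da * a, db * b])

    res = optimize.minimize(
        neg, np.log([a0, b0]), jac=True, method="L-BFGS-B",
        bounds=[(-7, 9)] * 2,
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_beta_mixture(
    values,
    n_components: int = 3,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> BetaMixtureResult:
    """EM fit of an ``n_components``-state beta mixture to beta values.

    The three states correspond to unmethylated / hemimethylated / methylated
    probes.  Values at exactly 0 or 1 are nudged inward by 1e-6.  The M-step
    solves the weighted beta likelihood exactly, so the log-likelihood trace
    is non-decreasing.  Initialization is method-of-moments on value
    quantile bins, making the fit deterministic.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 30:
        raise ValidationError("need at least 30 values to fit a beta mixture")
    if np.isnan(x).any() or x.min() < 0 or x.max() > 1:
        raise ValidationError("beta mixture input must be in [0, 1] with no NaN")
    x = _nudge(x)

    if np.ptp(x) < 1e-9:
        resp = np.zeros((x.size, n_components))
        resp[:, 0] = 1.0
        return BetaMixtureResult(
            a=np.full(n_components, 1.0),
            b=np.full(n_components, 1.0),
            weights=np.eye(n_components)[0],
            responsibilities=resp,
            assignments=np.zeros(x.size, dtype=int),
            log_likelihood=[],
            converged=True,
            degenerate=True,
        )

    order = np.sort(x)
    bins = np.array_split(order, n_components)
    a = np.empty(n_components)
    b = np.empty(n_components)
    for c, chunk in enumerate(bins):
        a[c], b[c] = _mom_beta(chunk)
    w = np.full(n_components, 1.0 / n_components)

    logx = np.log(x)
    log1mx = np.log1p(-x)
    ll_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        logpdf = np.column_stack(
            [
                (a[c] - 1) * logx + (b[c] - 1) * log1mx - special.betaln(a[c], b[c])
                for c in range(n_components)
            ]
        )
        logpdf += np.log(np.maximum(w, 1e-300))
        ll = float(special.logsumexp(logpdf, axis=1).sum())
        resp = np.exp(logpdf - special.logsumexp(logpdf, axis=1, keepdims=True))
        if ll_trace and abs(ll - ll_trace[-1]) < tol:
            ll_trace.append(ll)
            converged = True
            break
        ll_trace.append(ll)
        w = resp.mean(axis=0)
        for c in range(n_components):
            if resp[:, c].sum() < 1e-8:
                continue  # empty component: freeze its parameters
            a[c], b[c] = _mle_beta(resp[:, c], logx, log1mx, a[c], b[c])

    means = a / (a + b)
    rank = np.argsort(means, kind="stable")
    a, b, w = a[rank], b[rank], w[rank]
    resp = resp[:, rank]
    return BetaMixtureResult(
        a=a,
        b=b,
        weights=w,
        responsibilities=resp,
        assignments=np.argmax(resp, axis=1),
        log_likelihood=ll_trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# normalization to the gold standard
# ---------------------------------------------------------------------------

def _quantile_map(v: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    if v.size == ref_sorted.size:
        out[np.argsort(v, kind="stable")] = ref_sorted
        return out
    # General case: interpolate on plotting positions.
    ranks = stats.rankdata(v, method="average")
    q = (ranks - 0.5) / v.size
    pos = (np.arange(ref_sorted.size) + 0.5) / ref_sorted.size
    return np.interp(q, pos, ref_sorted)


def bmiq_normalize(
    m: BetaMatrix, ref: NormalizationReference, mode: str = "bmiq"
) -> BetaMatrix:
    """Adjust every sample's beta distribution toward the gold standard.

    ``mode="bmiq"``: fit three-state beta mixtures to the reference and to
    each sample, match states by ascending component mean, and push each
    value through its state's beta CDF to the matched reference component's
    quantile.  ``mode="quantile"``: plain rank-based quantile mapping onto
    the reference distribution.  Requires a complete matrix (impute first);
    output stays in [0, 1].  A sample whose mixture fit degenerates falls
    back to quantile mapping.
    """
    if mode not in {"bmiq", "quantile"}:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    if np.isnan(m.values).any():
        raise ValidationError("matrix must be complete before normalization")
    ref_vals = ref.aligned_to(m.probe_ids)
    ref_sorted = np.sort(ref_vals)

    out = np.empty_like(m.values)
    if mode == "quantile":
        for j in range(m.n_samples):
            out[:, j] = _quantile_map(m.values[:, j], ref_sorted)
    else:
        ref_fit = fit_beta_mixture(_nudge(ref_vals))
        for j in range(m.n_samples):
            v = _nudge(m.values[:, j])
            fit = fit_beta_mixture(v)
            if fit.degenerate or ref_fit.degenerate:
                out[:, j] = _quantile_map(m.values[:, j], ref_sorted)
                continue
            col = np.empty_like(v)
            for c in range(3):
                sel = fit.assignments == c
                if not sel.any():
                    continue
                u = stats.beta.cdf(v[sel], fit.a[c], fit.b[c])
                u = np.clip(u, 1e-12, 1 - 1e-12)
                col[sel] = stats.beta.ppf(u, ref_fit.a[c], ref_fit.b[c])
            out[:, j] = np.clip(col, 0.0, 1.0)
    return BetaMatrix(
        list(m.probe_ids), list(m.sample_ids), out, dict(m.platform_of_sample)
    )


# ---------------------------------------------------------------------------
# iterative PCA outlier removal
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _pc1_scores(values: np.ndarray) -> np.ndarray:
    """PC1 scores of samples (columns) after centering each probe."""
    xc = (values - values.mean(axis=1, keepdims=True)).T  # n x p
    gram = xc @ xc.T
    n = gram.shape[0]
    eigval, eigvec = linalg.eigh(gram, subset_by_index=[n - 1, n - 1])
    return eigvec[:, 0] * math.sqrt(max(float(eigval[0]), 0.0))


def pca_outlier_filter(
    m: BetaMatrix,
    fdr_threshold: float = 0.2,
    max_iter: int = 20,
) -> tuple[BetaMatrix, OutlierReport]:
    """Iteratively remove samples whose PC1 displacement is extreme.

    Per iteration: center probes, compute each sample's PC1 score, square its
    distance from the mean score, z-score those squared distances, convert to
    upper-tail Gaussian p-values, BH-adjust, and drop samples whose adjusted
    value falls below ``fdr_threshold``.  Stops when an iteration removes
    nothing or after ``max_iter`` rounds.
    """
    if np.isnan(m.values).any():
        raise ValidationError("matrix must be complete before outlier filtering")
    if m.n_samples < 10:
        raise ValidationError("need at least 10 samples for outlier filtering")

    current = m
    report = OutlierReport()
    for _ in range(max_iter):
        scores = _pc1_scores(current.values)
        d2 = (scores - scores.mean()) ** 2
        sd = d2.std()
        if sd == 0:
            break
        z = (d2 - d2.mean()) / sd
        p = stats.norm.sf(z)
        fdr = bh_adjust(p)
        flag = fdr < fdr_threshold
        if flag.all():
            raise ValidationError("outlier filter would remove every sample")
        if not flag.any():
            break
        removed = [s for s, f in zip(current.sample_ids, flag) if f]
        report.iterations.append(
            OutlierIteration(
                removed_sample_ids=removed,
                z_scores={s: float(v) for s, v in zip(current.sample_ids, z)},
                fdr_values={s: float(v) for s, v in zip(current.sample_ids, fdr)},
            )
        )
        keep = [s for s, f in zip(current.sample_ids, flag) if not f]
        current = current.subset_samples(keep)
    return current, report
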