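"""The child-specific methylation age clock.

Age (in months) is mapped through a piecewise transform F that is logarithmic
up to a "toddler age" knot (48 months by default) and linear past it:

    F(a) = log(a + 1) - log(T + 1)   for a <= T
    F(a) = (a - T) / (T + 1)         for a >  T

Both branches vanish at a = T, so F is continuous and strictly increasing.
The clock is an elastic-net linear model on beta values predicting F(age);
predictions are mapped back to months via the inverse transform.  Because
methylation change is fastest early in life, fitting on the F scale weights
infant months more heavily than adolescent months.

Dimensionality is cut before fitting with sure independence screening (SIS):
probes are ranked by the absolute Pearson correlation of their beta values
with F(age) and only the top ``floor(n / log n)`` enter the penalized fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .io import BetaMatrix, ClockModel, ValidationError

__all__ = [
    "TransformParams",
    "CVResult",
    "f_transform",
    "f_inverse",
    "sis_screen",
    "fit_clock",
    "predict_dnam_age",
]

DEFAULT_TODDLER_AGE = 48.0
DEFAULT_ALPHA = 0.48
#: Penalty strength the original clock was trained with (on standardized
#: predictors, glmnet convention); kept as the documented default even though
#: new fits normally re-select lambda by cross-validation.
DEFAULT_LAMBDA = 0.000954

PREDICTION_FLOOR_MONTHS = 0.1


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the age transform F (knot in months)."""

    toddler_age: float = DEFAULT_TODDLER_AGE

    def __post_init__(self) -> None:
        if not self.toddler_age > 0:
            raise ValidationError("toddler_age must be positive")


@dataclass
class CVResult:
    """Cross-validation summary for a clock fit.

    ``pooled_correlation`` and ``per_fold_error`` are computed from held-out
    predictions mapped back to months; errors are per-fold median absolute
    deviations between predicted and true age.
    """

    fold_assignments: dict[str, int]
    per_fold_error: list[float]
    pooled_correlation: float
    chosen_lambda: float
    mean_cv_mse: float = math.nan
    pooled_median_abs_error: float = math.nan
    heldout_predictions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the age transform
# ---------------------------------------------------------------------------

def f_transform(age_months, params: TransformParams = TransformParams()):
    """Map age in months to the transformed-age scale (scalar or array)."""
    a = np.asarray(age_months, dtype=float)
    if np.any(a <= -1.0):
        raise ValidationError("age must be > -1 month for the log branch")
    t = params.toddler_age
    out = np.where(
        a <= t,
        np.log1p(a) - math.log1p(t),
        (a - t) / (t + 1.0),
    )
    return float(out) if np.isscalar(age_months) else out


def f_inverse(t_value, params: TransformParams = TransformParams()):
    """Inverse of :func:`f_transform`: transformed age back to months."""
    t = np.asarray(t_value, dtype=float)
    knot = params.toddler_age
    # (knot+1)*e^t - 1 keeps f_inverse(0) == knot exact in floating point.
    out = np.where(
        t <= 0.0,
        (knot + 1.0) * np.exp(np.minimum(t, 0.0)) - 1.0,
        knot + t * (knot + 1.0),
    )
    return float(out) if np.isscalar(t_value) else out


# ---------------------------------------------------------------------------
# sure independence screening
# ---------------------------------------------------------------------------

def sis_screen(
    m: BetaMatrix,
    ages_months,
    params: TransformParams = TransformParams(),
    n_keep: int | str = "auto",
    return_scores: bool = False,
):
    """Rank probes by |Pearson r| with transformed age; keep the top n_keep.

    ``n_keep="auto"`` keeps ``floor(n_samples / log(n_samples))`` probes, the
    usual screening-literature default.  Zero-variance probes get correlation
    0 and can never outrank a probe with non-zero correlation; ties are broken
    by probe id.
    """
    ages = np.asarray(ages_months, dtype=float)
    if ages.shape != (m.n_samples,):
        raise ValidationError("ages length does not match sample count")
    if np.isnan(m.values).any():
        raise ValidationError("matrix must be complete (impute first)")
    y = f_transform(ages, params)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    x = m.values
    xc = x - x.mean(axis=1, keepdims=True)
    x_ss = np.einsum("ij,ij->i", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.sqrt(x_ss * y_ss)
    r[~np.isfinite(r)] = 0.0  # zero-variance probes (or constant age)

    if n_keep == "auto":
        n = m.n_samples
        n_keep = max(1, int(n / math.log(n))) if n > 2 else n
    n_keep = min(int(n_keep), m.n_probes)
    if n_keep < 1:
        raise ValidationError("n_keep must be >= 1")
    order = sorted(range(m.n_probes), key=lambda i: (-abs(r[i]), m.probe_ids[i]))
    kept = order[:n_keep]
    probes = [m.probe_ids[i] for i in kept]
    if return_scores:
        return probes, {m.probe_ids[i]: float(r[i]) for i in order}
    return probes


# ---------------------------------------------------------------------------
# elastic-net fitting
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray):
    """Center/scale columns; (near-)constant columns are mapped to zero so the
    raw-scale back-transform of their coefficients stays finite."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd <= 1e-10
    sd_safe = np.where(constant, 1.0, sd)
    xs = (x - mu) / sd_safe
    xs[:, constant] = 0.0
    return xs, mu, sd_safe


def _fit_at(
    xs: np.ndarray, y: np.ndarray, alpha: float, lam: float, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Fit on standardized predictors; return (coefs, intercept) on that scale."""
    if lam == 0.0:
        # Unpenalized: minimum-norm least squares (interpolates when p >= n).
        design = np.hstack([np.ones((xs.shape[0], 1)), xs])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        return sol[1:], float(sol[0])
    net = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=50_000, tol=tol
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs, y)
    return net.coef_.copy(), float(net.intercept_)


def _fit_path(xs: np.ndarray, y: np.ndarray, alpha: float, grid: np.ndarray):
    """Warm-started fits along a descending penalty grid.

    Yields (coefs, intercept) per grid point, in grid order.
    """
    net = ElasticNet(
        alpha=float(grid[0]), l1_ratio=alpha, fit_intercept=True,
        warm_start=True, max_iter=20_000, tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for g in grid:
            if g == 0.0:
                yield _fit_at(xs, y, alpha, 0.0)
                continue
            net.set_params(alpha=float(g))
            net.fit(xs, y)
            yield net.coef_.copy(), float(net.intercept_)


def _lambda_grid(xs, y, alpha, n_lambdas=60, min_ratio=1e-4):
    yc = y - y.mean()
    lam_max = np.abs(xs.T @ yc).max() / (len(y) * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def fit_clock(
    m: BetaMatrix,
    ages_months,
    params: TransformParams = TransformParams(),
    alpha: float = DEFAULT_ALPHA,
    lam: float | str = "cv",
    cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 60,
) -> tuple[ClockModel, CVResult]:
    """Fit the elastic-net clock on F(age); evaluate by k-fold CV.

    Minimizes ``(1/2n) sum (F(age_i) - b0 - x_i'b)^2 +
    lam * (alpha*|b|_1 + (1-alpha)/2*|b|_2^2)`` with predictors standardized
    internally (coefficients are returned on the raw beta scale).  With
    ``lam="cv"`` the penalty is chosen to minimize mean squared CV error in
    transformed-age units over a log-spaced grid; with a numeric ``lam`` the
    same folds still provide the held-out performance report.  ``lam=0``
    falls back to (minimum-norm) least squares.

    Returns the model refit on all samples at the chosen penalty plus the
    cross-validation result.
    """
    ages = np.asarray(ages_months, dtype=float)
    if ages.shape != (m.n_samples,):
        raise ValidationError("ages length does not match sample count")
    if np.isnan(m.values).any() or not np.isfinite(ages).all():
        raise ValidationError("non-finite input to fit_clock")
    n = m.n_samples
    if cv_folds == 0:
        # No cross-validation: fit once at a fixed penalty (training-set use).
        if lam == "cv":
            raise ValidationError("lambda selection by CV requires cv_folds >= 2")
        chosen = float(lam)
        cv = CVResult({}, [], math.nan, chosen)
    else:
        if n < 2 * cv_folds:
            raise ValidationError(
                f"need at least {2 * cv_folds} samples for {cv_folds}-fold CV"
            )
    x = m.values.T  # n x p
    y = f_transform(ages, params)
    xs, mu, sd = _standardize(x)

    if cv_folds > 0:
        if lam == "cv":
            grid = _lambda_grid(xs, y, alpha, n_lambdas)
        else:
            grid = np.array([float(lam)])

        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(kf.split(xs))
        cv_pred_t = np.full((len(grid), n), np.nan)  # held-out preds, F scale
        for tr, te in folds:
            xtr, mtr, str_ = _standardize(x[tr])
            xte = (x[te] - mtr) / str_
            ytr = y[tr]
            for gi, (coef, icpt) in enumerate(_fit_path(xtr, ytr, alpha, grid)):
                cv_pred_t[gi, te] = icpt + xte @ coef

        mse = ((cv_pred_t - y[None, :]) ** 2).mean(axis=1)
        best = int(np.argmin(mse))
        chosen = float(grid[best])

        pred_months = f_inverse(cv_pred_t[best], params)
        pred_months = np.maximum(pred_months, PREDICTION_FLOOR_MONTHS)
        fold_assignments: dict[str, int] = {}
        per_fold_error: list[float] = []
        for fold_no, (_, te) in enumerate(folds, start=1):
            for i in te:
                fold_assignments[m.sample_ids[i]] = fold_no
            per_fold_error.append(float(np.median(np.abs(pred_months[te] - ages[te]))))
        pooled_r = float(np.corrcoef(pred_months, ages)[0, 1]) if n > 1 else math.nan
        cv = CVResult(
            fold_assignments=fold_assignments,
            per_fold_error=per_fold_error,
            pooled_correlation=pooled_r,
            chosen_lambda=chosen,
            mean_cv_mse=float(mse[best]),
            pooled_median_abs_error=float(np.median(np.abs(pred_months - ages))),
            heldout_predictions={
                s: float(pred_months[i]) for i, s in enumerate(m.sample_ids)
            },
        )

    coef_s, icpt_s = _fit_at(xs, y, alpha, chosen)
    coef_raw = coef_s / sd
    intercept = icpt_s - float(coef_raw @ mu)
    keep_all = chosen == 0.0
    coefficients = {
        p: float(c)
        for p, c in zip(m.probe_ids, coef_raw)
        if keep_all or c != 0.0
    }
    model = ClockModel(
        intercept=intercept,
        coefficients=coefficients,
        toddler_age=params.toddler_age,
        alpha=alpha,
        lam=chosen,
        training_summary={
            "n_samples": n,
            "n_probes": m.n_probes,
            "n_nonzero": int(sum(c != 0.0 for c in coefficients.values())),
            "cv_folds": cv_folds,
            "cv_mean_mse": cv.mean_cv_mse,
            "cv_pooled_r": cv.pooled_correlation,
            "cv_median_abs_error_months": cv.pooled_median_abs_error,
            "seed": seed,
        },
    )
    return model, cv


def predict_dnam_age(
    model: ClockModel, m: BetaMatrix, floor_months: float = PREDICTION_FLOOR_MONTHS
) -> np.ndarray:
    """Predict DNA methylation age in months for every sample of ``m``.

    Every model probe must be present and observed for every sample; the
    linear predictor is mapped back through the inverse age transform and
    clipped below at ``floor_months``.
    """
    idx = m.probe_index()
    missing = [p for p in model.coefficients if p not in idx]
    if missing:
        raise ValidationError(
            f"{len(missing)} model probes absent from matrix: {missing[:5]}"
        )
    probes = list(model.coefficients)
    rows = [idx[p] for p in probes]
    sub = m.values[rows, :]
    if np.isnan(sub).any():
        bad = [m.sample_ids[j] for j in np.where(np.isnan(sub).any(axis=0))[0]]
        raise ValidationError(f"missing beta values for samples {bad[:5]}")
    coefs = np.array([model.coefficients[p] for p in probes])
    lin = model.intercept + coefs @ sub
    months = f_inverse(lin, TransformParams(model.toddler_age))
    return np.maximum(months, floor_months)
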