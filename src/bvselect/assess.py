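"""Calibration-quality measures and group statistical comparisons.

Beyond RMSE and AIC, fits are scored by a multi-dimensional measure: four
nonnegative residual features — absolute bias, residual standard
deviation, absolute trend of the residual over time, and absolute trend of
the residual over the measured BV range — are normalized to [0, 1] by the
pooled per-feature maximum across all subjects *and both models*, and
collapsed to the Euclidean distance U_d from the origin (the ideal fit).
Normalizing over the joint pool keeps U_d comparable between models.

Group comparisons mirror the study tables: paired t-tests between models
on per-subject metrics, Welch two-sample t-tests between fluid groups on
fitted parameters, and chi-squared tests on envelope-coverage proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import register_serializable
from .models import ValidationError

__all__ = [
    "FeatureVector",
    "GroupComparison",
    "rmse",
    "aic",
    "error_features",
    "normalize_features",
    "euclidean_distance",
    "compare_models",
    "compare_fluids",
    "compare_proportions",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("bias", "se_resid", "trend_time", "trend_range")


@register_serializable
@dataclass(frozen=True)
class FeatureVector:
    """Raw (and optionally normalized) residual features of one fit.

    Raw units: bias ml, se_resid ml, trend_time ml/min, trend_range
    dimensionless.  All entries are nonnegative so the origin is the ideal
    point.
    """

    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (4,):
            raise ValidationError("a feature vector has exactly 4 entries")
        if np.any(raw < 0):
            raise ValidationError("raw features must be nonnegative")
        object.__setattr__(self, "raw", raw)
        if self.normalized is not None:
            nz = np.asarray(self.normalized, dtype=float)
            if nz.shape != (4,) or np.any(nz < 0) or np.any(nz > 1):
                raise ValidationError("normalized features must lie in [0, 1]^4")
            object.__setattr__(self, "normalized", nz)


@register_serializable
@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group statistical test."""

    metric: str
    test: str            # paired_t | welch_t | chi_squared
    statistic: float
    p_value: float
    n: int
    group_means: tuple[float, float] | None = None
    flag: str | None = None   # e.g. zero-variance warning

    def __post_init__(self) -> None:
        if self.flag is None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def rmse(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-squared error between two equal-length series (ml)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 1:
        raise ValidationError("rmse needs two equal-length series of length >= 1")
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, −2L* + 2P."""
    return -2.0 * loglik + 2.0 * n_params


def _ols_slope(x: np.ndarray, y: np.ndarray, what: str) -> float:
    sx = x - x.mean()
    denom = sx @ sx
    if denom <= 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
        warnings.warn(f"degenerate regressor for {what}; trend set to 0",
                      stacklevel=3)
        return 0.0
    return float((sx @ (y - y.mean())) / denom)


def error_features(measured: np.ndarray, predicted: np.ndarray,
                   times: np.ndarray) -> FeatureVector:
    """Raw residual features of one fit (K >= 3 required for the trends)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (measured.shape == predicted.shape == times.shape):
        raise ValidationError("measured, predicted, times must share a shape")
    if measured.size < 3:
        raise ValidationError("error features need K >= 3 observations")
    resid = measured - predicted
    return FeatureVector(raw=np.array([
        abs(float(resid.mean())),
        float(np.std(resid, ddof=1)),
        abs(_ols_slope(times, resid, "trend over time")),
        abs(_ols_slope(measured, resid, "trend over BV range")),
    ]))


def normalize_features(pool: list[FeatureVector]) -> list[FeatureVector]:
    """Normalize each feature by its maximum over the pooled fits.

    The pool must contain every fit being compared (all subjects × both
    models); a pooled maximum of 0 leaves that feature at 0 for all.
    """
    if not pool:
        raise ValidationError("feature pool must be nonempty")
    raw = np.stack([fv.raw for fv in pool])
    denom = raw.max(axis=0)
    denom = np.where(denom > 0, denom, 1.0)
    return [FeatureVector(raw=fv.raw, normalized=fv.raw / denom) for fv in pool]


def euclidean_distance(fv: FeatureVector) -> float:
    """U_d = sqrt(Σ f_i²) of the normalized features; ranges over [0, 2]."""
    if fv.normalized is None:
        raise ValidationError("euclidean_distance needs normalized features")
    return float(np.linalg.norm(fv.normalized))


def compare_models(values_a: np.ndarray, values_b: np.ndarray,
                   metric: str = "") -> GroupComparison:
    """Paired t-test between per-subject metric values of two models."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired comparison needs equal-length samples, n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0.0:
        return GroupComparison(metric=metric, test="paired_t", statistic=np.nan,
                               p_value=np.nan, n=a.size,
                               group_means=(float(a.mean()), float(b.mean())),
                               flag="zero-variance paired differences")
    t, p = stats.ttest_rel(a, b)
    return GroupComparison(metric=metric, test="paired_t", statistic=float(t),
                           p_value=float(p), n=a.size,
                           group_means=(float(a.mean()), float(b.mean())))


def compare_fluids(values_lr: np.ndarray, values_hex: np.ndarray,
                   metric: str = "") -> GroupComparison:
    """Welch (unequal-variance) two-sample t-test between fluid groups."""
    a = np.asarray(values_lr, dtype=float)
    b = np.asarray(values_hex, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(metric=metric, test="welch_t", statistic=float(t),
                           p_value=float(p), n=a.size + b.size,
                           group_means=(float(a.mean()), float(b.mean())))


def compare_proportions(hits_a: int, trials_a: int, hits_b: int,
                        trials_b: int, metric: str = "") -> GroupComparison:
    """Chi-squared test (no continuity correction) on two hit proportions."""
    if min(trials_a, trials_b) < 1 or not (0 <= hits_a <= trials_a
                                           and 0 <= hits_b <= trials_b):
        raise ValidationError("need 0 <= hits <= trials and trials >= 1")
    table = np.array([[hits_a, trials_a - hits_a],
                      [hits_b, trials_b - hits_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        # all hits or all misses in both groups: no association testable
        return GroupComparison(metric=metric, test="chi_squared", statistic=0.0,
                               p_value=1.0, n=trials_a + trials_b,
                               group_means=(hits_a / trials_a, hits_b / trials_b))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(metric=metric, test="chi_squared",
                           statistic=float(chi2), p_value=float(p),
                           n=trials_a + trials_b,
                           group_means=(hits_a / trials_a, hits_b / trials_b))
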