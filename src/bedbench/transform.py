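"""Reciprocal normalization of bed rates and distribution diagnostics.

Bed rates are right-skewed; modelling the reciprocal 1/rate brings the
outcome close to normal. The map is strictly decreasing on (0, inf), so it
is its own inverse, coefficient signs invert their interpretation, and
interval endpoints swap when mapped back to the rate scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, NonPhysicalIntervalError, ValidationError

__all__ = [
    "inverse_transform",
    "back_transform_interval",
    "back_transform_point",
    "moment_diagnostics",
    "MomentDiagnostics",
]


def inverse_transform(y):
    """Reciprocal transform y -> 1/y, elementwise; an involution on (0, inf)."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("reciprocal transform requires strictly positive values")
    out = 1.0 / arr
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def back_transform_point(y_prime: float) -> float:
    """Map a transformed-scale prediction back to the rate scale."""
    if y_prime <= 0:
        raise NonPhysicalIntervalError(
            f"transformed-scale prediction {y_prime} is non-positive; "
            "its reciprocal bed rate is undefined"
        )
    return 1.0 / y_prime


def back_transform_interval(lo_prime: float, hi_prime: float) -> tuple[float, float]:
    """Map a transformed-scale interval back to the rate scale.

    Because the reciprocal is decreasing, the endpoints swap:
    (lo', hi') -> (1/hi', 1/lo'). Degenerate intervals (lo' == hi') map to a
    degenerate point. A non-positive lower bound has no finite rate-scale
    image and raises :class:`NonPhysicalIntervalError`; callers that want a
    right-open interval should catch it and flag the estimate.
    """
    if lo_prime > hi_prime:
        raise ValidationError(f"interval bounds out of order: ({lo_prime}, {hi_prime})")
    if lo_prime <= 0:
        raise NonPhysicalIntervalError(
            f"transformed lower bound {lo_prime} is non-positive; the rate-scale "
            "interval is right-open"
        )
    return 1.0 / hi_prime, 1.0 / lo_prime


@dataclass(frozen=True)
class MomentDiagnostics:
    """Bias-corrected sample skewness/excess kurtosis with standard errors."""

    skewness: float
    kurtosis: float  # excess
    se_skewness: float
    se_kurtosis: float
    n: int


def moment_diagnostics(values) -> MomentDiagnostics:
    """Normality diagnostics for a sample: corrected skewness and kurtosis.

    Uses the bias-corrected estimators that mainstream statistics packages
    print, with the usual normal-theory standard errors

        SE_skew = sqrt(6 n (n-1) / ((n-2)(n+1)(n+3)))
        SE_kurt = 2 SE_skew sqrt((n^2 - 1) / ((n-3)(n+5)))
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 4:
        raise ValidationError(f"moment diagnostics need n >= 4, got n = {n}")
    skew = float(stats.skew(arr, bias=False))
    kurt = float(stats.kurtosis(arr, fisher=True, bias=False))
    se_skew = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = 2.0 * se_skew * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))
    return MomentDiagnostics(
        skewness=skew, kurtosis=kurt, se_skewness=se_skew, se_kurtosis=se_kurt, n=n
    )
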