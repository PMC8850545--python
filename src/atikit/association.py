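"""Correlation and detrending statistics for index-versus-survey validation.

Weekly index and survey series share strong secular trends (both decayed
roughly linearly over the study window), so a raw Pearson correlation can be
an artefact of non-independence. The validation therefore pairs each raw
correlation with a residual correlation: every series is regressed on time,
and the correlation is re-estimated on the residuals. A positive raw r that
reverses sign after detrending flags a trend-driven association.

Confidence intervals for r use the Fisher z-transform with standard error
1/sqrt(n-3); p-values are two-sided from the t distribution with n-2 df.
``n`` is always the number of paired observations actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "DetrendResult",
    "AssociationError",
    "pearson_with_ci",
    "detrend_on_time",
    "residual_correlation",
]


class AssociationError(ValueError):
    """Degenerate input to a correlation or detrending operation."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with a Fisher-z confidence interval."""

    r: float
    n: int
    ci_lower: float
    ci_upper: float
    p: float
    conf: float = 0.95

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ci_lower <= self.r + 1e-12
                and self.r - 1e-12 <= self.ci_upper <= 1.0):
            raise AssociationError(
                f"CI [{self.ci_lower}, {self.ci_upper}] does not bracket r={self.r}"
            )


@dataclass(frozen=True)
class DetrendResult:
    """OLS-on-time fit: standardized and raw slopes plus residuals.

    ``beta_std`` is the slope of the z-scored series on the z-scored week
    index (it equals the series-time correlation, hence lies in [-1, 1]);
    ``residuals`` are on the raw scale of the input series.
    """

    beta_std: float
    ci_lower: float
    ci_upper: float
    p: float
    beta_raw: float
    intercept_raw: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        res = np.asarray(self.residuals, dtype=float)
        res.setflags(write=False)
        object.__setattr__(self, "residuals", res)


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.any(~np.isfinite(arr)):
        raise AssociationError(f"{name} contains non-finite values")
    return arr


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation with Fisher-z CI and two-sided t-test p-value.

    Requires two equal-length, non-constant series of at least 4 paired
    observations. For |r| = 1 the Fisher transform degenerates and the CI
    collapses onto r.
    """
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if len(x) != len(y):
        raise AssociationError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 4:
        raise AssociationError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("constant input series")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        lo = hi = r
        p = 0.0
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(0.5 + conf / 2.0)
        lo = float(np.tanh(z - crit * se))
        hi = float(np.tanh(z + crit * se))
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, ci_lower=lo, ci_upper=hi, p=p, conf=conf)


def detrend_on_time(series, conf: float = 0.95) -> DetrendResult:
    """Regress a weekly series on its time index and keep the residuals.

    The reported slope is standardized (z-scored series on z-scored time), so
    it is comparable across measures and bounded in [-1, 1]; residuals are
    returned on the raw scale for downstream residual correlations. Residuals
    sum to zero and are exactly uncorrelated with time.
    """
    y = _as_series(series, "series")
    n = len(y)
    if n < 4:
        raise AssociationError(f"need at least 4 observations, got {n}")
    if np.ptp(y) == 0:
        raise AssociationError("constant input series")
    t = np.arange(n, dtype=float)

    tc = t - t.mean()
    beta_raw = float(tc @ (y - y.mean()) / (tc @ tc))
    intercept = float(y.mean() - beta_raw * t.mean())
    residuals = y - (intercept + beta_raw * t)

    sy = y.std(ddof=1)
    st = t.std(ddof=1)
    beta_std = beta_raw * st / sy
    # OLS slope se on the standardized scale, t-based CI with n-2 df
    if abs(beta_std) >= 1.0 - 1e-15:
        lo = hi = beta_std
        p = 0.0
    else:
        se = np.sqrt((1.0 - beta_std**2) / (n - 2))
        crit = stats.t.ppf(0.5 + conf / 2.0, df=n - 2)
        lo = float(beta_std - crit * se)
        hi = float(beta_std + crit * se)
        tstat = beta_std / se
        p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return DetrendResult(
        beta_std=float(beta_std), ci_lower=lo, ci_upper=hi, p=p,
        beta_raw=beta_raw, intercept_raw=intercept, residuals=residuals,
    )


def residual_correlation(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation between the time-detrended residuals of two series."""
    rx = detrend_on_time(x, conf=conf).residuals
    ry = detrend_on_time(y, conf=conf).residuals
    return pearson_with_ci(rx, ry, conf=conf)
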