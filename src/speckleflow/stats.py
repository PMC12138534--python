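"""Group-comparison statistics applied to the pipeline outputs.

Thin, typed wrappers over the standard tests a physiologist would apply to
per-animal metrics: Welch's two-sample t-test (CBF medians, NVC peak/AUC),
the two-sample Kolmogorov-Smirnov test (vessel-diameter distributions,
either raw per-segment samples or mode-normalized histogram curves), and a
descriptive logarithmic trend fit mean = a + b*ln(age) used to summarize
CBF against age (guide-the-eye only; no inference is attached).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "LogTrendFit",
    "two_sample_t",
    "ks_two_sample",
    "ks_histogram_curves",
    "fit_log_trend",
]


@dataclass
class GroupSample:
    """A labelled sample of scalar metric values for one group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class LogTrendFit:
    """Least-squares fit of mean = a + b*ln(age_months)."""

    a: float
    b: float
    rss: float

    def predict(self, ages_months: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages_months, dtype=float)
        if np.any(ages <= 0):
            raise ValueError("ages must be positive")
        return self.a + self.b * np.log(ages)


def two_sample_t(a: GroupSample, b: GroupSample) -> TestResult:
    """Welch's two-sample t-test (unequal variances, Welch-Satterthwaite
    degrees of freedom), two-sided.

    Degenerate zero-variance samples: equal means give p = 1 by convention;
    unequal means give the smallest representable p.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("t-test needs n >= 2 in both groups")
    if a.values.var(ddof=1) == 0 and b.values.var(ddof=1) == 0:
        if a.values.mean() == b.values.mean():
            return TestResult("welch_t", 0.0, 1.0, a.n, b.n)
        sign = np.sign(a.values.mean() - b.values.mean())
        return TestResult("welch_t", float(sign * np.inf), np.nextafter(0, 1), a.n, b.n)
    t, p = sps.ttest_ind(a.values, b.values, equal_var=False)
    return TestResult("welch_t", float(t), float(p), a.n, b.n)


def ks_two_sample(
    a: GroupSample, b: GroupSample, method: str = "auto"
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |F_a - F_b| over the
    pooled sample points, two-sided p-value from scipy (exact for small
    samples under ``method='auto'``, asymptotic with effective
    n = n_a*n_b/(n_a+n_b) under ``method='asymp'``)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("KS test needs nonempty samples")
    d, p = sps.ks_2samp(a.values, b.values, method=method)
    return TestResult("ks_2samp", float(d), float(p), a.n, b.n)


def ks_histogram_curves(a: GroupSample, b: GroupSample, method: str = "auto") -> TestResult:
    """Figure-parity variant: KS applied to mode-normalized histogram
    curves rather than raw samples. The inputs are the normalized bin
    heights of the two groups' diameter histograms (same binning)."""
    return ks_two_sample(a, b, method=method)


def fit_log_trend(ages_months: np.ndarray, means: np.ndarray) -> LogTrendFit:
    """Fit mean = a + b*ln(age) by least squares on the log-transformed axis.

    With exactly two distinct ages the fit interpolates the points.
    Descriptive only — the curve guides the eye across sparse age groups.
    """
    ages = np.asarray(ages_months, dtype=float)
    means = np.asarray(means, dtype=float)
    if ages.shape != means.shape or ages.size < 2:
        raise ValueError("need matching arrays with at least two points")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive for a logarithmic fit")
    if np.unique(ages).size < 2:
        raise ValueError("need at least two distinct ages")
    X = np.column_stack([np.ones_like(ages), np.log(ages)])
    coef, *_ = np.linalg.lstsq(X, means, rcond=None)
    resid = means - X @ coef
    return LogTrendFit(a=float(coef[0]), b=float(coef[1]), rss=float(resid @ resid))
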