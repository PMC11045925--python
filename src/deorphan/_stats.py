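"""Shared statistical primitives.

Thin wrappers around scipy with explicit handling of the degenerate cases
that routinely occur in small-replicate assay data (zero within-group
variance, single observations), plus the interquartile-range outlier rule
used for replicate QC.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "coefficient_of_variation",
    "two_sample_t",
    "one_sample_t",
    "iqr_fences",
    "flag_outliers_iqr",
    "p_to_stars",
]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent (sd with ddof=1 over mean).

    Returns nan when the mean is zero or fewer than two values are given.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


def _p_from_alternative(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample t-test returning (t, p).

    Equal-variance (Student) by default; Welch with ``equal_var=False``.
    Zero pooled variance is resolved deterministically: identical means give
    p = 1, separated means give p = 0 (the data are then noiseless).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        t = np.inf if x.mean() > y.mean() else -np.inf
        if alternative == "two-sided":
            return float(t), 0.0
        if alternative == "greater":
            return float(t), 0.0 if t > 0 else 1.0
        return float(t), 0.0 if t < 0 else 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(
    x: Sequence[float], popmean: float, alternative: str = "two-sided"
) -> tuple[float, float]:
    """One-sample t-test of ``mean(x)`` against ``popmean``, returning (t, p).

    Zero variance resolves deterministically as in :func:`two_sample_t`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if x.var(ddof=1) == 0.0:
        if x.mean() == popmean:
            return 0.0, 1.0
        t = np.inf if x.mean() > popmean else -np.inf
        if alternative == "two-sided":
            return float(t), 0.0
        if alternative == "greater":
            return float(t), 0.0 if t > 0 else 1.0
        return float(t), 0.0 if t < 0 else 1.0
    res = stats.ttest_1samp(x, popmean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def iqr_fences(values: Sequence[float], k: float = 1.5) -> tuple[float, float]:
    """Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics
    (numpy's default quantile convention).
    """
    x = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def flag_outliers_iqr(
    values: Sequence[float], k: float = 1.5, min_n: int = 4
) -> np.ndarray:
    """Boolean mask of values outside the Tukey fences.

    With fewer than ``min_n`` observations nothing is flagged: quartiles of
    two or three points carry no information about spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if x.size < min_n:
        return np.zeros(x.size, dtype=bool)
    lo, hi = iqr_fences(x, k=k)
    return (x < lo) | (x > hi)


def p_to_stars(p: float, levels: tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
    """Map a p-value to the conventional significance stars (ns/*/**/***)."""
    if not np.isfinite(p):
        return "ns"
    if p <= levels[2]:
        return "***"
    if p <= levels[1]:
        return "**"
    if p <= levels[0]:
        return "*"
    return "ns"
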