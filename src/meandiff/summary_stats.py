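"""Per-group and two-group sufficient statistics.

Every estimator in this package consumes either a single :class:`SampleSummary`
(mean, unbiased variance, sample size) or a :class:`TwoSampleDesign` pairing
two of them.  Summaries can be built from raw data vectors or directly from
(estimated) parameters, so the data-based and parameter-based entry points
share one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SampleSummary",
    "TwoSampleDesign",
    "summarize",
    "pooled_sd",
    "welch_t",
    "welch_df",
]


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one normal sample.

    Parameters
    ----------
    mean : float
        Sample mean, in the units of the measurement.
    variance : float
        Unbiased (n−1 denominator) sample variance, in squared units.
    n : int
        Sample size, ≥ 1.
    """

    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if not (math.isfinite(self.variance) and self.variance >= 0):
            raise ValueError(f"variance must be finite and >= 0, got {self.variance}")

    @property
    def sd(self) -> float:
        """Unbiased sample standard deviation."""
        return math.sqrt(self.variance)


def summarize(values: Sequence[float]) -> SampleSummary:
    """Build a :class:`SampleSummary` from a raw data vector.

    The variance uses the n−1 denominator and a two-pass algorithm (mean
    first, then centred sum of squares) for numerical stability.

    Raises
    ------
    ValueError
        If fewer than two values are given or any value is non-finite.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError("insufficient sample: need at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in sample")
    mean = float(arr.mean())
    ss = float(np.sum((arr - mean) ** 2))
    return SampleSummary(mean=mean, variance=ss / (arr.size - 1), n=int(arr.size))


def pooled_sd(g1: SampleSummary, g2: SampleSummary) -> float:
    """Pooled standard deviation, the df-weighted average of the variances.

    S_pooled = sqrt{ [s1²(n1−1) + s2²(n2−1)] / (n1+n2−2) }.
    """
    m = g1.n + g2.n - 2
    if m <= 0:
        raise ValueError("pooled SD requires n1+n2-2 > 0")
    return math.sqrt((g1.variance * (g1.n - 1) + g2.variance * (g2.n - 1)) / m)


def _unpooled_se2(g1: SampleSummary, g2: SampleSummary) -> float:
    if g1.n < 2 or g2.n < 2:
        raise ValueError("both groups need n >= 2")
    se2 = g1.variance / g1.n + g2.variance / g2.n
    if se2 <= 0:
        raise ValueError("degenerate samples: both variances are zero")
    return se2


def welch_t(g1: SampleSummary, g2: SampleSummary) -> float:
    """Welch's t statistic, (Ȳ1−Ȳ2)/sqrt(s1²/n1 + s2²/n2)."""
    return (g1.mean - g2.mean) / math.sqrt(_unpooled_se2(g1, g2))


def welch_df(g1: SampleSummary, g2: SampleSummary) -> float:
    """Welch–Satterthwaite approximate degrees of freedom.

    f = (s1²/n1 + s2²/n2)² / [ s1⁴/{n1²(n1−1)} + s2⁴/{n2²(n2−1)} ]

    Returned as a real number — never rounded: the small-sample bias
    correction is evaluated at this fractional df.
    """
    se2 = _unpooled_se2(g1, g2)
    den = g1.variance**2 / (g1.n**2 * (g1.n - 1)) + g2.variance**2 / (
        g2.n**2 * (g2.n - 1)
    )
    return se2**2 / den


@dataclass(frozen=True)
class TwoSampleDesign:
    """A pair of group summaries with the derived two-sample quantities."""

    group1: SampleSummary
    group2: SampleSummary

    def __post_init__(self) -> None:
        if self.group1.n < 2 or self.group2.n < 2:
            raise ValueError("two-sample designs need n >= 2 per group")

    @classmethod
    def from_data(cls, values1: Sequence[float], values2: Sequence[float]) -> "TwoSampleDesign":
        return cls(summarize(values1), summarize(values2))

    @classmethod
    def from_params(
        cls,
        mean1: float,
        mean2: float,
        var1: float,
        var2: float,
        n1: int,
        n2: int,
    ) -> "TwoSampleDesign":
        """Build a design from per-group (mean, variance, n) parameters."""
        return cls(SampleSummary(mean1, var1, n1), SampleSummary(mean2, var2, n2))

    @property
    def n_tilde(self) -> float:
        """Effective sample size ñ = n1·n2/(n1+n2); always < min(n1, n2)."""
        return self.group1.n * self.group2.n / (self.group1.n + self.group2.n)

    @property
    def r_ratio(self) -> float:
        """Sample-size ratio r = n1/n2."""
        return self.group1.n / self.group2.n

    @property
    def pooled_df(self) -> int:
        """Classical pooled degrees of freedom m = n1+n2−2."""
        return self.group1.n + self.group2.n - 2

    @property
    def s_pooled(self) -> float:
        return pooled_sd(self.group1, self.group2)

    @property
    def f_welch(self) -> float:
        return welch_df(self.group1, self.group2)

    @property
    def welch_t(self) -> float:
        return welch_t(self.group1, self.group2)
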