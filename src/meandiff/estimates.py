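"""High-level estimate objects: point estimate + variance + CI in one call.

These are the entry points the command line (and most users) go through.
Each returns an :class:`EffectSizeEstimate` bundling the point estimate,
its plug-in sampling variance, the noncentral-t confidence interval, the
degrees of freedom and the reporting options used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .noncentral_ci import NcpSearchConfig, ci_one_sample, ci_two_sample
from .point_estimators import (
    c_biased,
    c_unbiased,
    e_biased,
    e_unbiased,
    hedges_d,
    hedges_g,
)
from .summary_stats import SampleSummary, TwoSampleDesign
from .variance_estimators import var_biased_two_sample, var_c, var_d, var_e

__all__ = ["EffectSizeEstimate", "estimate_d", "estimate_e", "estimate_c"]


@dataclass(frozen=True)
class EffectSizeEstimate:
    """An effect-size estimate with its uncertainty.

    value, variance : the point estimate and its plug-in sampling variance
    ci_lower, ci_upper : noncentral-t confidence interval at level 1−alpha
    df : degrees of freedom of the underlying t statistic
    family : "d", "e" or "c"
    corrected : whether the small-sample J correction was applied
    alpha : two-sided type-I error rate of the interval
    """

    value: float
    variance: float
    ci_lower: float
    ci_upper: float
    df: float
    family: str
    corrected: bool
    alpha: float

    def as_vector(self) -> tuple:
        """(estimate, variance, ci_lower, ci_upper) in reporting order."""
        return (self.value, self.variance, self.ci_lower, self.ci_upper)


def _config(alpha: float) -> NcpSearchConfig:
    return NcpSearchConfig(alpha=alpha)


def estimate_d(
    design: TwoSampleDesign, alpha: float = 0.05, unbiased: bool = True
) -> EffectSizeEstimate:
    """Pooled-SD effect size d (or g when ``unbiased=False``) with variance
    and CI.  The CI pivot is g·√ñ on n1+n2−2 df."""
    cfg = _config(alpha)
    m = float(design.pooled_df)
    t_obs = hedges_g(design) * math.sqrt(design.n_tilde)
    lo, hi = ci_two_sample(t_obs, m, design.n_tilde, corrected=unbiased, config=cfg)
    value = hedges_d(design) if unbiased else hedges_g(design)
    variance = var_d(design) if unbiased else var_biased_two_sample(design, "d")
    return EffectSizeEstimate(value, variance, lo, hi, m, "d", unbiased, alpha)


def estimate_e(
    design: TwoSampleDesign, alpha: float = 0.05, unbiased: bool = True
) -> EffectSizeEstimate:
    """Welch-based heteroscedastic effect size e (or its biased version)
    with variance and CI.  The CI pivot is Welch's t on f df."""
    cfg = _config(alpha)
    f = design.f_welch
    lo, hi = ci_two_sample(design.welch_t, f, design.n_tilde, corrected=unbiased, config=cfg)
    value = e_unbiased(design) if unbiased else e_biased(design)
    variance = var_e(design) if unbiased else var_biased_two_sample(design, "e")
    return EffectSizeEstimate(value, variance, lo, hi, f, "e", unbiased, alpha)


def estimate_c(
    sample: SampleSummary, constant: float, alpha: float = 0.05, unbiased: bool = True
) -> EffectSizeEstimate:
    """One-sample effect size c (mean vs known constant) with variance and
    CI.  The pivot is c_biased·√(n−1) on n−1 df."""
    cfg = _config(alpha)
    lo, hi = ci_one_sample(sample, constant, corrected=unbiased, config=cfg)
    value = c_unbiased(sample, constant) if unbiased else c_biased(sample, constant)
    variance = var_c(sample, constant, corrected=unbiased)
    return EffectSizeEstimate(
        value, variance, lo, hi, float(sample.n - 1), "c", unbiased, alpha
    )


def estimate_d_from_data(values1: Sequence[float], values2: Sequence[float], **kw):
    return estimate_d(TwoSampleDesign.from_data(values1, values2), **kw)


def estimate_e_from_data(values1: Sequence[float], values2: Sequence[float], **kw):
    return estimate_e(TwoSampleDesign.from_data(values1, values2), **kw)
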