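"""Effect-size parameters and point estimators.

Parameters (population quantities)
----------------------------------
delta_param      δ   = (μ1−μ2)/σ                common-variance SMD
epsilon_param    ϵ_r = (μ1−μ2)/√((σ1²+rσ2²)/(r+1))   heteroscedastic SMD,
                 r the sample-size ratio n1/n2
gamma_param      γ   = (μ−C)/σ1                 mean vs known constant
delta_q_param    δ'_q = (μ1−μ2)/√((qσ1²+σ2²)/(1+q)), q = (n1−1)/(n2−1);
                 the parameter the pooled statistic g drifts to under
                 unequal variances

Statistics
----------
hedges_g         g = (Ȳ1−Ȳ2)/S_pooled           biased, pooled SD
hedges_d         d = J(n1+n2−2)·g                unbiased under equal σ
glass_delta      Δ = (Ȳ_E−Ȳ_C)/S_C              control-group SD only
bonett_delta_hat δ̂ = (Ȳ1−Ȳ2)/√((s1²+s2²)/2)     unweighted-average SD
e_biased         t_w/√ñ                          Welch-based, biased
e_unbiased       e = e_biased·J(f)               unbiased estimator of ϵ_r
c_biased         (Ȳ1−C)/s1                       one-sample, biased
c_unbiased       c = c_biased·J(n1−1)            unbiased estimator of γ
c_prime          (C−Ȳ1)·J(n1−1)/s1 = −c          constant-centred view
"""

from __future__ import annotations

import math

from .bias_correction import correction_j
from .summary_stats import SampleSummary, TwoSampleDesign, welch_t

__all__ = [
    "hedges_g",
    "hedges_d",
    "glass_delta",
    "bonett_delta_hat",
    "e_biased",
    "e_unbiased",
    "c_biased",
    "c_unbiased",
    "c_prime",
    "delta_param",
    "epsilon_param",
    "gamma_param",
    "delta_q_param",
]


# ---------------------------------------------------------------- statistics

def hedges_g(design: TwoSampleDesign) -> float:
    """Pooled-SD standardized mean difference g (biased)."""
    sp = design.s_pooled
    if sp <= 0:
        raise ValueError("zero pooled SD")
    return (design.group1.mean - design.group2.mean) / sp


def hedges_d(design: TwoSampleDesign) -> float:
    """Bias-corrected pooled-SD effect size d = J(n1+n2−2)·g."""
    return correction_j(design.pooled_df) * hedges_g(design)


def glass_delta(experimental: SampleSummary, control: SampleSummary) -> float:
    """Glass's Δ: mean difference over the control group's SD.

    The caller designates the control group explicitly; there is no
    heuristic ordering.
    """
    if control.n < 2 or control.variance <= 0:
        raise ValueError("control group needs n >= 2 and positive variance")
    return (experimental.mean - control.mean) / control.sd


def bonett_delta_hat(g1: SampleSummary, g2: SampleSummary) -> float:
    """Bonett's two-group statistic δ̂ = (Ȳ1−Ȳ2)/√((s1²+s2²)/2).

    Equals g when n1 = n2; its population parameter is undefined in
    general.
    """
    s2 = (g1.variance + g2.variance) / 2.0
    if s2 <= 0:
        raise ValueError("both variances are zero")
    return (g1.mean - g2.mean) / math.sqrt(s2)


def e_biased(design: TwoSampleDesign) -> float:
    """Welch-based effect size t_w/√ñ (biased estimator of ϵ_r)."""
    return welch_t(design.group1, design.group2) / math.sqrt(design.n_tilde)


def e_unbiased(design: TwoSampleDesign) -> float:
    """Unbiased heteroscedastic effect size e = e_biased·J(f).

    J is evaluated at the fractional Welch–Satterthwaite df f.
    """
    return e_biased(design) * correction_j(design.f_welch)


def c_biased(sample: SampleSummary, constant: float) -> float:
    """One-sample effect size (Ȳ−C)/s (biased estimator of γ)."""
    if sample.n < 2 or sample.variance <= 0:
        raise ValueError("need n >= 2 and positive variance")
    return (sample.mean - constant) / sample.sd


def c_unbiased(sample: SampleSummary, constant: float) -> float:
    """Unbiased one-sample effect size c = c_biased·J(n−1)."""
    if sample.n < 3:
        raise ValueError("unbiased one-sample effect size needs n >= 3")
    return c_biased(sample, constant) * correction_j(sample.n - 1)


def c_prime(sample: SampleSummary, constant: float) -> float:
    """Constant-centred effect size c′ = (C−Ȳ)·J(n−1)/s = −c."""
    return -c_unbiased(sample, constant)


# ---------------------------------------------------------------- parameters

def delta_param(mu1: float, mu2: float, sigma: float) -> float:
    """Common-variance SMD parameter δ = (μ1−μ2)/σ."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (mu1 - mu2) / sigma


def epsilon_param(mu1: float, mu2: float, sigma1: float, sigma2: float, r: float) -> float:
    """Heteroscedastic SMD parameter ϵ_r = (μ1−μ2)/√((σ1²+rσ2²)/(r+1)).

    ``r`` is the sample-size ratio n1/n2 of the design the parameter is
    tied to; ϵ_r reduces to δ when σ1 = σ2.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    denom2 = (sigma1**2 + r * sigma2**2) / (r + 1.0)
    if denom2 <= 0:
        raise ValueError("degenerate denominator: both sigmas are zero")
    return (mu1 - mu2) / math.sqrt(denom2)


def gamma_param(mu: float, constant: float, sigma1: float) -> float:
    """One-sample SMD parameter γ = (μ−C)/σ1."""
    if sigma1 <= 0:
        raise ValueError("sigma must be positive")
    return (mu - constant) / sigma1


def delta_q_param(mu1: float, mu2: float, sigma1: float, sigma2: float, q: float) -> float:
    """δ'_q = (μ1−μ2)/√((qσ1²+σ2²)/(1+q)), the parameter estimated by the
    pooled statistic under unequal variances, with q = (n1−1)/(n2−1)."""
    if q <= 0:
        raise ValueError("q must be positive")
    denom2 = (q * sigma1**2 + sigma2**2) / (1.0 + q)
    if denom2 <= 0:
        raise ValueError("degenerate denominator: both sigmas are zero")
    return (mu1 - mu2) / math.sqrt(denom2)
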