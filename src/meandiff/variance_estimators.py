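"""Plug-in sampling variances of the effect-size estimators.

All formulas come from the second moment of a noncentral-t variate with the
unknown effect-size parameter replaced by its *biased* point estimate
(g, e_biased or c_biased).  For an unbiased estimator θ = J(ν)·T/√k with
T ~ nct(ν, param·√k):

    var(θ) = ν/(ν−2) · J²(ν) · (1/k + param²) − param²,

and for the uncorrected statistic T/√k, whose mean is param/J(ν):

    var = ν/(ν−2) · (1/k + param²) − param²/J²(ν).

The scale k is ñ for two-sample families and n1−1 for the one-sample
family.
"""

from __future__ import annotations

from .bias_correction import correction_j
from .point_estimators import c_biased, e_biased, hedges_g
from .summary_stats import SampleSummary, TwoSampleDesign

__all__ = ["var_d", "var_e", "var_c", "var_biased_two_sample"]


def _var_corrected(df: float, k: float, param: float) -> float:
    j2 = correction_j(df) ** 2
    return df / (df - 2.0) * j2 * (1.0 / k + param**2) - param**2


def _var_uncorrected(df: float, k: float, param: float) -> float:
    j2 = correction_j(df) ** 2
    return df / (df - 2.0) * (1.0 / k + param**2) - param**2 / j2


def var_d(design: TwoSampleDesign) -> float:
    """Sampling variance of the unbiased pooled-SD effect size d.

    Uses df m = n1+n2−2 and scale ñ, with g plugged into the parameter
    slot.
    """
    m = design.pooled_df
    if m <= 2:
        raise ValueError("variance undefined: need n1+n2-2 > 2")
    return _var_corrected(m, design.n_tilde, hedges_g(design))


def var_e(design: TwoSampleDesign) -> float:
    """Sampling variance of the unbiased Welch-based effect size e.

    var(e) = f/(f−2)·J²(f)·(1/ñ + ϵ²) − ϵ², with the Welch–Satterthwaite
    df f and e_biased plugged in for the parameter ϵ_r.
    """
    f = design.f_welch
    if f <= 2:
        raise ValueError("variance undefined: Welch df must exceed 2")
    return _var_corrected(f, design.n_tilde, e_biased(design))


def var_c(sample: SampleSummary, constant: float, corrected: bool = True) -> float:
    """Sampling variance of the one-sample effect size (mean vs constant).

    The statistic is scaled by √(n1−1), so ν = n1−1 and k = n1−1:

    * corrected:  (n1−1)/(n1−3)·J²(n1−1)·(1/(n1−1) + γ²) − γ²
    * biased:     (1 + (n1−1)·c²)/(n1−3) − c²/J²(n1−1)

    with c_biased plugged in for γ in both branches.
    """
    if sample.n <= 3:
        raise ValueError("variance undefined: need n > 3")
    nu = sample.n - 1
    c = c_biased(sample, constant)
    if corrected:
        return _var_corrected(nu, nu, c)
    return _var_uncorrected(nu, nu, c)


def var_biased_two_sample(design: TwoSampleDesign, family: str) -> float:
    """Sampling variance of the *uncorrected* two-sample statistic.

    ``family`` is ``"d"`` (pooled statistic g, df = n1+n2−2) or ``"e"``
    (Welch statistic e_biased, df = f).
    """
    if family == "d":
        df = float(design.pooled_df)
        theta = hedges_g(design)
    elif family == "e":
        df = design.f_welch
        theta = e_biased(design)
    else:
        raise ValueError(f"unknown family {family!r}; expected 'd' or 'e'")
    if df <= 2:
        raise ValueError("variance undefined: df must exceed 2")
    return _var_uncorrected(df, design.n_tilde, theta)
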