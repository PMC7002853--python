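"""Exact effect-size confidence intervals via noncentral-t inversion.

A standardized mean difference divided by its scale is a noncentral-t
variate (exactly for the pooled and one-sample statistics, approximately
for the Welch statistic at the Satterthwaite df).  A confidence interval
for the effect size therefore follows from inverting the noncentral-t CDF
in its noncentrality parameter (ncp):

* ``ncp_L`` solves  P(T ≤ t_obs; df, ncp) = 1 − α/2,
* ``ncp_H`` solves  P(T ≤ t_obs; df, ncp) = α/2,

and the interval on the effect-size scale is [ncp_L/√k, ncp_H/√k] with
k = ñ (two-sample) or n1−1 (one-sample), optionally multiplied by the
bias-correction coefficient J when the corrected estimator is reported.

The CDF is strictly decreasing in the ncp, so each root is unique; it is
found by geometric bracket expansion followed by bisection.  The solver is
vectorised so that simulation studies can invert tens of thousands of
intervals per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import special

from .bias_correction import correction_j
from .summary_stats import SampleSummary

__all__ = ["NcpSearchConfig", "find_ncp", "ncp_bounds", "ci_two_sample", "ci_one_sample"]


@dataclass(frozen=True)
class NcpSearchConfig:
    """Tolerances and bracketing policy for the ncp root find.

    alpha : two-sided type-I error rate of the interval (default 0.05).
    tol : absolute tolerance on the noncentral parameter (default 1e-8).
    max_expand : maximum geometric bracket doublings (default 60).
    """

    alpha: float = 0.05
    tol: float = 1e-8
    max_expand: int = 60

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


DEFAULT_CONFIG = NcpSearchConfig()


def _nct_cdf(t, df, ncp):
    return special.nctdtr(df, ncp, t)


def _find_ncp_vec(t_obs, df, target_prob, tol, max_expand):
    """Vectorised monotone bisection for the ncp root (arrays broadcast)."""
    t, df, p = np.broadcast_arrays(
        np.atleast_1d(np.asarray(t_obs, float)),
        np.asarray(df, float),
        np.asarray(target_prob, float),
    )
    t = np.array(t, float)
    lo = t - 1.0
    hi = t + 1.0
    # CDF decreases in ncp: push lo down until cdf(lo) >= p, hi up until
    # cdf(hi) <= p, doubling the step each time.
    step = np.ones_like(t)
    for _ in range(max_expand):
        bad = _nct_cdf(t, df, lo) < p
        if not bad.any():
            break
        lo[bad] -= step[bad]
        step[bad] *= 2.0
    else:
        raise RuntimeError("ncp bracket not found (lower)")
    step = np.ones_like(t)
    for _ in range(max_expand):
        bad = _nct_cdf(t, df, hi) > p
        if not bad.any():
            break
        hi[bad] += step[bad]
        step[bad] *= 2.0
    else:
        raise RuntimeError("ncp bracket not found (upper)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        left = _nct_cdf(t, df, mid) >= p
        lo = np.where(left, mid, lo)
        hi = np.where(left, hi, mid)
        if float(np.max(hi - lo)) < tol:
            break
    return 0.5 * (lo + hi)


def find_ncp(t_obs, df, target_prob, config: NcpSearchConfig | None = None):
    """Noncentrality parameter at which the noncentral-t CDF of ``t_obs``
    equals ``target_prob``.

    Scalar inputs return a float; array inputs broadcast and return an
    ndarray.  The root is unique because the CDF is strictly decreasing in
    the ncp.
    """
    cfg = config or DEFAULT_CONFIG
    out = _find_ncp_vec(t_obs, df, target_prob, cfg.tol, cfg.max_expand)
    if np.ndim(t_obs) == 0 and np.ndim(df) == 0 and np.ndim(target_prob) == 0:
        return float(out[0])
    return out


def ncp_bounds(t_obs, df, alpha, config: NcpSearchConfig | None = None):
    """(ncp_L, ncp_H) enclosing the true noncentrality at level 1−α."""
    cfg = config or DEFAULT_CONFIG
    lo = find_ncp(t_obs, df, 1.0 - alpha / 2.0, cfg)
    hi = find_ncp(t_obs, df, alpha / 2.0, cfg)
    return lo, hi


def ci_two_sample(
    t_obs: float,
    df: float,
    scale_n: float,
    corrected: bool = True,
    config: NcpSearchConfig | None = None,
) -> Tuple[float, float]:
    """Two-sample effect-size CI from a t statistic.

    ``t_obs`` is the pooled-variance statistic g·√ñ (df = n1+n2−2) or
    Welch's t (df = f); ``scale_n`` is ñ.  The raw interval is
    [ncp_L/√ñ, ncp_H/√ñ]; when ``corrected`` both ends are multiplied by
    J(df) to put them on the scale of the unbiased estimator.
    """
    cfg = config or DEFAULT_CONFIG
    lo, hi = ncp_bounds(t_obs, df, cfg.alpha, cfg)
    scale = 1.0 / math.sqrt(scale_n)
    if corrected:
        scale *= correction_j(df)
    return lo * scale, hi * scale


def ci_one_sample(
    sample: SampleSummary,
    constant: float,
    corrected: bool = True,
    config: NcpSearchConfig | None = None,
) -> Tuple[float, float]:
    """One-sample (mean vs constant) effect-size CI.

    The pivot is t = (Ȳ−C)/sqrt(s²/(n−1)) = c_biased·√(n−1) with df = n−1;
    the interval is [ncp_L/√(n−1), ncp_H/√(n−1)], J(n−1)-scaled when
    ``corrected``.
    """
    cfg = config or DEFAULT_CONFIG
    if sample.n < 2:
        raise ValueError("one-sample CI needs n >= 2")
    if sample.variance <= 0:
        raise ValueError("zero sample variance")
    nu = sample.n - 1
    t_obs = (sample.mean - constant) / sample.sd * math.sqrt(nu)
    lo, hi = ncp_bounds(t_obs, nu, cfg.alpha, cfg)
    scale = 1.0 / math.sqrt(nu)
    if corrected:
        scale *= correction_j(nu)
    return lo * scale, hi * scale
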