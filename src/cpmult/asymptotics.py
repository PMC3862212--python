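"""Large-sample behaviour of the multinomial log-mass and the limiting
p-value.

For X^n ~ Multinomial(n, θ) with all θ_j > 0, the centered statistic

    −2 log p(X^n|θ) − c_n,   c_n = (K−1) log(2πn) + Σ_j log θ_j,

converges in distribution to χ² on K−1 degrees of freedom.  As MT sample
sizes diverge the posterior collapses to the true θ, so the conditional
predictive p-value is asymptotically h(V) with V ~ χ²_{K−1}:

    h(v) = P( f(U) ≤ f(V) | V = v ),   U, V iid χ²_{K−1},

f the χ² density.  By the probability integral transform h(V) is uniform,
which is the asymptotic-validity guarantee.  h also serves as a fast
large-sample approximation to the test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .distributions import multinomial_logpmf

_ROOT_TOL = 1e-10


@dataclass
class CenteredStat:
    """The centered −2 log multinomial mass and its reference df."""

    value: float
    df: int
    c_n: float


def centering_constant(n: int, theta) -> float:
    """c_n = (K−1)·log(2πn) + Σ_j log θ_j."""
    theta = np.asarray(theta, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    if (theta <= 0).any():
        raise ValueError("all theta_j must be positive")
    K = theta.shape[0]
    return float((K - 1) * np.log(2 * np.pi * n) + np.log(theta).sum())


def centered_logmass(x, n: int, theta) -> CenteredStat:
    """−2 log p(x|θ) − c_n, asymptotically χ²_{K−1}."""
    theta = np.asarray(theta, dtype=float)
    lp = multinomial_logpmf(x, n, theta)
    return CenteredStat(value=-2.0 * lp - centering_constant(n, theta),
                        df=theta.shape[0] - 1,
                        c_n=centering_constant(n, theta))


def limiting_pvalue(v: float, df: int) -> float:
    """h(v) = P(f(U) ≤ f(v)) for U ~ χ²_df.

    For df ≤ 2 the density is monotone decreasing, so h(v) = P(U ≥ v).  For
    df ≥ 3 the density is unimodal with mode df−2: the level set
    {u : f(u) ≤ f(v)} is [0, v_lo] ∪ [v_hi, ∞) where f(v_lo) = f(v_hi) = f(v)
    on either side of the mode, located by bracketed bisection.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if v < 0:
        raise ValueError("v must be non-negative")
    dist = chi2(df)
    if df <= 2:
        return float(dist.sf(v))
    mode = df - 2.0
    if v == 0.0:
        return 0.0
    lv = dist.logpdf(v)
    if not np.isfinite(lv) or v == mode:
        return 1.0

    def g(u):
        return dist.logpdf(u) - lv

    if v < mode:
        v_lo = v
        hi = mode + max(1.0, mode)
        while g(hi) > 0:
            hi = mode + 2 * (hi - mode)
        v_hi = brentq(g, mode, hi, xtol=_ROOT_TOL)
    else:
        v_hi = v
        # strictly increasing on (0, mode); f(0+) = 0 < f(v)
        v_lo = brentq(g, 1e-300, mode, xtol=_ROOT_TOL)
    return float(dist.cdf(v_lo) + dist.sf(v_hi))


def limiting_pvalues(vs, df: int) -> np.ndarray:
    return np.array([limiting_pvalue(float(v), df) for v in np.asarray(vs)])
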