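"""Probability kernels of the sampling hierarchy.

The MT-MC counts follow a Dirichlet-multinomial conditional on the latent
bottleneck survivors Z (parameters φ·z_t), which are themselves Poisson;
all other counts are multinomial.  Everything is computed on the log scale:
totals near 100 overflow raw factorials.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

ALPHA0_CAP = 1e8


@dataclass
class DirichletApprox:
    """Moment-matched Dirichlet approximation to a posterior over the simplex."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.alpha <= 0).any():
            raise ValueError("Dirichlet parameters must be positive")

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha0


def _check_counts(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() != n:
        raise ValueError(f"counts sum to {x.sum()}, expected n={n}")
    return x


def multinomial_logpmf(x, n: int, theta) -> float:
    """log P(X=x) for X ~ Multinomial(n, θ).

    Returns -inf when some x_t > 0 with θ_t = 0.
    """
    x = _check_counts(x, n)
    theta = np.asarray(theta, dtype=float)
    if (theta < 0).any():
        raise ValueError("theta must be non-negative")
    with np.errstate(divide="ignore"):
        s = xlogy(x, theta).sum()  # xlogy(0,0)=0; -inf iff some x_t>0, θ_t=0
    if not np.isfinite(s):
        return float("-inf")
    return float(gammaln(n + 1) - gammaln(x + 1).sum() + s)


def dirichlet_multinomial_logpmf(y, n: int, a) -> float:
    """log P(Y=y) for Y ~ DirichletMultinomial(n, a).

    Zero parameters follow the Γ(a_t)→∞ limit: the factor for category t is
    1 when y_t = 0 and the whole pmf is 0 when y_t > 0 (a clone absent from
    the bottleneck cannot be sequenced).
    """
    y = _check_counts(y, n)
    a = np.asarray(a, dtype=float)
    if (a < 0).any():
        raise ValueError("parameters must be non-negative")
    a0 = a.sum()
    if a0 == 0:
        if n == 0:
            return 0.0
        raise ValueError("all parameters zero with positive total count")
    if ((a == 0) & (y > 0)).any():
        return float("-inf")
    pos = a > 0
    yp, ap = y[pos], a[pos]
    return float(
        gammaln(n + 1) + gammaln(a0) - gammaln(n + a0)
        + (gammaln(ap + yp) - gammaln(yp + 1) - gammaln(ap)).sum()
    )


def dm_logpmf_rows(Y: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Vectorized Dirichlet-multinomial log-pmf, one value per row of Y,
    with a single strictly positive parameter vector `a`."""
    Y = np.asarray(Y)
    a = np.asarray(a, dtype=float)
    n = Y.sum(axis=1)
    a0 = a.sum()
    return (
        gammaln(n + 1) + gammaln(a0) - gammaln(n + a0)
        + (gammaln(a + Y) - gammaln(Y + 1) - gammaln(a)).sum(axis=1)
    )


def dm_conditional_moments(n: int, z, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the DM counts given the latent survivors z.

    mean_t = n·μ_t with μ_t = z_t/Σz;
    var_t  = n·μ_t(1−μ_t)·(1 + (n−1)/(φ·Σz))  — the variance-inflation factor.
    """
    z = np.asarray(z, dtype=float)
    zsum = z.sum()
    if zsum <= 0:
        raise ValueError("sum of latent counts must be positive")
    if phi <= 0:
        raise ValueError("phi must be positive")
    mu = z / zsum
    mean = n * mu
    var = n * mu * (1 - mu) * (1 + (n - 1) / (phi * zsum))
    return mean, var


def collapse_categories(obj, partition: dict):
    """Sum counts within collapsed categories; the DM family is closed under
    this operation (with summed parameters).

    `obj` is either a (categories, vector) pair or a CountTable; `partition`
    maps each fine category to its collapsed label.  Output order is the
    first-appearance order of the collapsed labels.
    """
    from .datamodel import CountTable  # local import to avoid cycle

    if isinstance(obj, CountTable):
        cats, mat = obj.categories, obj.counts
    else:
        cats, mat = obj
        mat = np.atleast_2d(np.asarray(mat)).T if np.asarray(mat).ndim == 1 else np.asarray(mat)
    missing = [c for c in cats if c not in partition]
    if missing:
        raise KeyError(f"categories {missing} not covered by the partition")
    order: list = []
    for c in cats:
        if partition[c] not in order:
            order.append(partition[c])
    out = np.zeros((len(order), mat.shape[1]), dtype=mat.dtype)
    for i, c in enumerate(cats):
        out[order.index(partition[c])] += mat[i]
    if isinstance(obj, CountTable):
        return CountTable([str(o) for o in order], obj.samples, out, obj.source_tag)
    vec = np.asarray(obj[1])
    return order, (out[:, 0] if vec.ndim == 1 else out)


def fit_dirichlet_moments(theta_draws: np.ndarray) -> DirichletApprox:
    """Method-of-moments Dirichlet fit to posterior draws on the simplex.

    Per category with mean m_t in (0,1) and positive sample variance v_t the
    implied precision is α0_t = m_t(1−m_t)/v_t − 1; these are aggregated by
    the mean-weighted average and the common precision is capped at 1e8.
    α_t = m_t·α0.
    """
    D = np.asarray(theta_draws, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValueError("need a G×K matrix with G ≥ 2")
    if not np.allclose(D.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must lie on the simplex")
    m = D.mean(axis=0)
    v = D.var(axis=0, ddof=1)
    ok = (m > 0) & (m < 1) & (v > 0)
    if not ok.any():
        warnings.warn("degenerate posterior draws; precision capped", RuntimeWarning)
        a0 = ALPHA0_CAP
    else:
        per_cat = m[ok] * (1 - m[ok]) / v[ok] - 1.0
        a0 = float(np.sum(m[ok] * per_cat) / np.sum(m[ok]))
        if a0 > ALPHA0_CAP:
            warnings.warn("moment precision exceeds cap; capped", RuntimeWarning)
            a0 = ALPHA0_CAP
        a0 = max(a0, 1e-6)
    return DirichletApprox(np.maximum(m, 1e-300) * a0)
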