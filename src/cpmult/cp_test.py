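"""The conditional predictive p-value.

Split the data into the WT piece X (pooled multinomial) and the MT piece Y
(overdispersed MC counts plus SC counts).  Condition on Y only, form the
posterior predictive ordinate p(x|y) = ∫ P(X=x|θ) p(θ|Y=y) dθ, and report

    p_cp(x, y) = P{ p(X^rep|y) ≤ p(x|y) | Y=y },

estimated with one multinomial replicate X^rep per saved posterior θ draw.
The predictive ordinate itself is evaluated analytically after a
method-of-moments Dirichlet approximation to p(θ|Y=y): the integral of a
multinomial against a Dirichlet is a Dirichlet-multinomial ordinate.  The
same fitted Dirichlet is used for the observed and every replicated
ordinate, since all are ordinates of one fixed conditional law.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Dataset, pool_wildtype
from .distributions import (DirichletApprox, dirichlet_multinomial_logpmf,
                            dm_logpmf_rows, fit_dirichlet_moments)
from .posterior import ConfigurationError, PosteriorDraws


@dataclass
class TestResult:
    """A p-value with its provenance."""

    pvalue: float
    method: str
    mc_size: int
    seed: int | None = None
    observed_ordinate: float | None = None
    auxiliary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0,1]")
        if self.mc_size <= 0:
            raise ValueError("Monte Carlo size must be positive")

    def to_dict(self) -> dict:
        return {
            "pvalue": self.pvalue,
            "method": self.method,
            "mc_size": self.mc_size,
            "seed": self.seed,
            "observed_ordinate": self.observed_ordinate,
            "auxiliary": self.auxiliary,
        }


def predictive_ordinate(x, approx: DirichletApprox) -> float:
    """log p(x|y) under the moment-matched Dirichlet posterior: the ordinate
    of a Dirichlet-multinomial(Σx, α)."""
    x = np.asarray(x)
    if x.shape[0] != approx.alpha.shape[0]:
        raise ValueError(
            f"count vector has {x.shape[0]} categories, approximation has "
            f"{approx.alpha.shape[0]}"
        )
    return dirichlet_multinomial_logpmf(x, int(x.sum()), approx.alpha)


def sample_predictive_replicates(draws: PosteriorDraws, m: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """One X^rep ~ Multinomial(m, θ^(g)) per saved draw; marginally these are
    posterior-predictive replicates."""
    if draws.G == 0:
        raise ConfigurationError("no posterior draws")
    if m < 0:
        raise ValueError("total must be non-negative")
    return rng.multinomial(m, draws.thetas)


def conditional_predictive_pvalue(dataset: Dataset, draws: PosteriorDraws,
                                  rng: np.random.Generator) -> TestResult:
    """Estimate p_cp from posterior draws fit on the dataset's MT data.

    Ties count toward the event (the inequality is ≤); with G draws the
    estimate lives on {0, 1/G, …, 1} and is ≥ 1/G whenever a replicate ties
    the observed ordinate exactly.
    """
    if draws.G == 0:
        raise ConfigurationError("no posterior draws")
    x, m = pool_wildtype(dataset)
    approx = fit_dirichlet_moments(draws.thetas)
    o_obs = predictive_ordinate(x, approx)
    reps = sample_predictive_replicates(draws, m, rng)
    o_rep = dm_logpmf_rows(reps, approx.alpha)
    pvalue = float(np.mean(o_rep <= o_obs))
    return TestResult(
        pvalue=pvalue, method="conditional-predictive", mc_size=draws.G,
        seed=draws.seed, observed_ordinate=float(o_obs),
        auxiliary={
            "alpha0": approx.alpha0,
            "pooled_wt_total": m,
            "acceptance": draws.acceptance,
        },
    )
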