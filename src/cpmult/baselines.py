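"""Baseline tests: Fisher's exact test on the pooled K×2 table, and a
likelihood-ratio test with forward-simulated marginal likelihoods.

Fisher's test conditions on the per-type margin S = X + Y; the conditional
law of X is multivariate hypergeometric ("generalized hypergeometric"), and
the p-value is the ordinate criterion
P{ p(X^rep|s) ≤ p(x|s) | S=s }.  It is exact without overdispersion but
deflates badly in its presence — that is the comparison the conditional
predictive p-value is built to fix.

The LR test approximates MLEs of (θ, φ) by posterior means (separately
under the null's common θ and the alternative's split θ), marginalizes the
latent bottleneck counts Z by forward simulation, and refers
Λ = 2(ℓ_alt − ℓ_null) to χ² on K−1 degrees of freedom (the alternative
frees one extra simplex vector).
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, multivariate_hypergeom

from .cp_test import TestResult
from .datamodel import Dataset, pool_mutant, pool_wildtype
from .distributions import multinomial_logpmf
from .posterior import ConfigurationError, PosteriorDraws, run_sampler

ENUM_LIMIT = 1_000_000
_TIE_TOL = 1e-9


def fisher_ordinate(x, y) -> float:
    """log of the conditional probability of column x given the margins of
    the K×2 table (x, y): the multivariate hypergeometric ordinate."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    s = x + y
    return float(multivariate_hypergeom.logpmf(x, m=s, n=int(x.sum())))


def _count_tables(s: np.ndarray, m: int) -> int:
    """Number of tables with the given margins: #{x : 0 ≤ x_t ≤ s_t, Σx = m},
    by dynamic programming (capped at ENUM_LIMIT + 1)."""
    counts = np.zeros(m + 1, dtype=np.int64)
    counts[0] = 1
    for st in s:
        new = np.zeros(m + 1, dtype=np.int64)
        for tot in range(m + 1):
            if counts[tot]:
                hi = min(int(st), m - tot)
                new[tot:tot + hi + 1] += counts[tot]
        counts = np.minimum(new, ENUM_LIMIT + 1)
    return int(counts[m])


def _enumerate_pvalue(x: np.ndarray, s: np.ndarray, m: int) -> float:
    o_obs = fisher_ordinate(x, s - x)
    K = len(s)
    total = 0.0
    buf: list[list[int]] = []

    def flush():
        nonlocal total
        if buf:
            o = multivariate_hypergeom.logpmf(np.asarray(buf, dtype=np.int64),
                                              m=s, n=m)
            total += float(np.exp(o[o <= o_obs + _TIE_TOL]).sum())
            buf.clear()

    stack = [(0, m, [])]
    while stack:
        t, rem, prefix = stack.pop()
        if t == K - 1:
            if rem <= s[t]:
                buf.append(prefix + [rem])
                if len(buf) >= 20_000:
                    flush()
            continue
        tail = int(s[t + 1:].sum())
        lo = max(0, rem - tail)
        hi = min(int(s[t]), rem)
        for v in range(lo, hi + 1):
            stack.append((t + 1, rem - v, prefix + [v]))
    flush()
    return min(total, 1.0)


def fisher_mc_pvalue(x, y, reps: int = 100_000,
                     rng: np.random.Generator | None = None) -> TestResult:
    """Fisher's exact test by the ordinate criterion.

    Exact enumeration over the margin-constrained table space when it has at
    most 1e6 tables; otherwise Monte Carlo with `reps` tables drawn from the
    conditional null, ties counted toward the event.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    s = x + y
    m = int(x.sum())
    n_tables = _count_tables(s, m)
    if n_tables <= ENUM_LIMIT:
        p = _enumerate_pvalue(x, s, m)
        return TestResult(pvalue=p, method="fisher-exact-enumeration",
                          mc_size=n_tables,
                          observed_ordinate=fisher_ordinate(x, y),
                          auxiliary={"tables": n_tables})
    if rng is None:
        rng = np.random.default_rng()
    if reps < 10_000:
        raise ConfigurationError("need at least 1e4 Monte Carlo tables")
    o_obs = fisher_ordinate(x, y)
    hits = 0
    block = 200_000
    done = 0
    while done < reps:
        b = min(block, reps - done)
        tables = multivariate_hypergeom.rvs(m=s, n=m, size=b, random_state=rng)
        o = multivariate_hypergeom.logpmf(tables, m=s, n=m)
        hits += int(np.sum(o <= o_obs + _TIE_TOL))
        done += b
    return TestResult(pvalue=hits / reps, method="fisher-montecarlo",
                      mc_size=reps, observed_ordinate=float(o_obs),
                      auxiliary={"hits": hits, "tables": n_tables})


def fisher_test(dataset: Dataset, reps: int = 100_000,
                rng: np.random.Generator | None = None) -> TestResult:
    """Fisher's test on the pooled K×2 table: WT (MC+SC) vs MT (MC+SC)."""
    x, _ = pool_wildtype(dataset)
    y, _ = pool_mutant(dataset)
    return fisher_mc_pvalue(x, y, reps=reps, rng=rng)


# ---------------------------------------------------------------------------
# Likelihood-ratio test with simulated marginal likelihood

def approx_marginal_loglik(dataset: Dataset, theta, phi: float, sims: int,
                           rng: np.random.Generator,
                           include_sc: bool = True,
                           include_wt: bool = True,
                           theta_wt=None) -> float:
    """Data log-likelihood at (θ, φ), marginalizing the latent survivors.

    Per MT-MC sample i, p(y^mc_i | θ, φ) = E[P(y^mc_i|Z) | ΣZ > 0] is
    estimated by Monte Carlo over Z ~ Π_t Poisson(s_i θ_t f_i) conditioned
    on a nonempty bottleneck (an empty culture yields no sequencing run, the
    same convention the simulator uses; the conditioning constant
    1−exp(−s_i f_i) does not depend on (θ, φ), so it cancels from likelihood
    ratios).  Averaging is on the probability scale through a log-sum-exp.
    SC and WT multinomial terms are exact; `theta_wt` (default θ) evaluates
    the WT term, which lets the alternative hypothesis free a separate WT
    frequency vector.
    """
    if sims < 100:
        raise ConfigurationError("sims < 100: estimator variance too high")
    theta = np.asarray(theta, dtype=float)
    if phi <= 0:
        raise ValueError("phi must be positive")
    total = 0.0
    mc = dataset.table("MT-MC")
    if mc is not None:
        for j, name in enumerate(mc.samples):
            yv = mc.counts[:, j]
            n = int(yv.sum())
            if n == 0:
                continue
            if name not in dataset.meta:
                raise ConfigurationError(f"no metadata for MT-MC sample {name!r}")
            lam = dataset.meta[name].sf * theta
            Z = rng.poisson(lam, size=(sims, len(lam)))
            alive = Z.sum(axis=1) > 0
            n_alive = int(alive.sum())
            if n_alive == 0:
                raise ConfigurationError(
                    f"sample {name!r}: no nonempty bottleneck draws at "
                    f"s·f = {dataset.meta[name].sf:g}"
                )
            Z = Z[alive]
            a = phi * Z
            ok = ~((a == 0) & (yv > 0)).any(axis=1)
            lp = np.full(n_alive, -np.inf)
            if ok.any():
                # per-row DM log-pmf; rows violating the support give 0 mass
                A = a[ok]
                a0 = A.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t1 = gammaln(A + yv) - gammaln(A)
                t1[A == 0] = 0.0  # then y_t = 0 by the support check
                lp[ok] = (gammaln(n + 1) + gammaln(a0) - gammaln(n + a0)
                          + (t1 - gammaln(yv + 1.0)).sum(axis=1))
            total += float(logsumexp(lp) - np.log(n_alive))
    if include_sc and dataset.table("MT-SC") is not None:
        sc = dataset.table("MT-SC")
        for j in range(sc.S):
            col = sc.counts[:, j]
            total += multinomial_logpmf(col, int(col.sum()), theta)
    if include_wt:
        tw = theta if theta_wt is None else np.asarray(theta_wt, dtype=float)
        x, m = pool_wildtype(dataset)
        total += multinomial_logpmf(x, m, tw)
    return total


def lr_test(dataset: Dataset, null_draws: PosteriorDraws,
            alt_draws: tuple[PosteriorDraws, PosteriorDraws], sims: int,
            rng: np.random.Generator) -> TestResult:
    """Approximate likelihood-ratio test.

    `null_draws` must come from a fit to all the data under one common θ;
    `alt_draws` is the (MT-fit, WT-fit) pair.  Posterior means stand in for
    MLEs; Λ = 2(ℓ_alt − ℓ_null) is referred to χ²_{K−1}.
    """
    K = dataset.K
    th_null = null_draws.thetas.mean(axis=0)
    phi_null = float(null_draws.phis.mean())
    mt_draws, wt_draws = alt_draws
    th_mt = mt_draws.thetas.mean(axis=0)
    phi_mt = float(mt_draws.phis.mean())
    th_wt = wt_draws.thetas.mean(axis=0)
    # common random numbers for the two marginal-likelihood estimates
    seed_pair = rng.integers(2**31)
    l_null = approx_marginal_loglik(dataset, th_null, phi_null, sims,
                                    np.random.default_rng(seed_pair))
    l_alt = approx_marginal_loglik(dataset, th_mt, phi_mt, sims,
                                   np.random.default_rng(seed_pair),
                                   theta_wt=th_wt)
    lam = 2.0 * (l_alt - l_null)
    aux = {"lambda": lam, "df": K - 1, "loglik_null": l_null,
           "loglik_alt": l_alt}
    if not np.isfinite(lam) or lam < 0:
        warnings.warn("non-positive or undefined LR statistic "
                      "(simulation/plug-in artifact); reporting p = 1",
                      RuntimeWarning)
        return TestResult(pvalue=1.0, method="likelihood-ratio", mc_size=sims,
                          auxiliary=aux)
    p = float(chi2.sf(lam, K - 1))
    return TestResult(pvalue=p, method="likelihood-ratio", mc_size=sims,
                      auxiliary=aux)


def lr_test_from_dataset(dataset: Dataset, draws: int = 4000,
                         burnin: int = 1000, sims: int = 10_000,
                         seed: int = 0) -> TestResult:
    """Convenience wrapper: run the three posterior fits then `lr_test`.

    Null: common θ from all components (MT-MC, MT-SC, WT).  Alternative: θ_mt
    from the MT data, θ_wt from the WT data alone.
    """
    rng = np.random.default_rng(seed)
    null_draws = run_sampler(dataset, draws=draws, burnin=burnin,
                             seed=int(rng.integers(2**31)),
                             components=("mt_mc", "mt_sc", "wt"))
    mt_draws = run_sampler(dataset, draws=draws, burnin=burnin,
                           seed=int(rng.integers(2**31)),
                           components=("mt_mc", "mt_sc"))
    wt_draws = run_sampler(dataset, draws=draws, burnin=burnin,
                           seed=int(rng.integers(2**31)), components=("wt",))
    res = lr_test(dataset, null_draws, (mt_draws, wt_draws), sims, rng)
    res.seed = seed
    return res
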