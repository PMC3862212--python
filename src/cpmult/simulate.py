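"""Synthetic data from the bottleneck/growth hierarchy, and the
operating-characteristics harness (type-I error and power).

A simulated sample i draws latent survivors Z_{i,t} ~ Poisson(s_i·θ^mt_t·f_i),
MT-MC counts Y^mc_i ~ DirichletMultinomial(n_i^mc, φ·Z_i), MT-SC counts
Y^sc_i ~ Multinomial(n_i^sc, θ^mt), and WT counts X^mc_i, X^sc_i
multinomial with θ^wt.  Under the null θ^mt = θ^wt.

The default experiment configuration matches the J-region study: six
samples, sequencing depths equal to the observed per-sample totals, type
frequencies and overdispersion taken as posterior means from a fit to the
J-region data, and bottleneck sizes s = 1e6, f = 1e-5 (the documented
defaults; the study's own per-sample values were not published).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kstest

from .cp_test import conditional_predictive_pvalue
from .datamodel import CountTable, Dataset, SampleMeta, load_fixture_jregion
from .posterior import ConfigurationError, run_sampler

MAX_REDRAWS = 10_000


@dataclass
class SimConfig:
    """Study conditions for one simulation scenario."""

    categories: list[str]
    theta_wt: np.ndarray
    theta_mt: np.ndarray
    phi: float
    s: np.ndarray          # per-sample cells treated
    f: np.ndarray          # per-sample mutant frequency
    m_mc: np.ndarray       # WT-MC sequencing depths
    m_sc: np.ndarray
    n_mc: np.ndarray       # MT-MC sequencing depths
    n_sc: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("theta_wt", "theta_mt", "s", "f", "m_mc", "m_sc",
                     "n_mc", "n_sc"):
            setattr(self, name, np.asarray(getattr(self, name)))
        for th in (self.theta_wt, self.theta_mt):
            if th.shape[0] != len(self.categories) or (th <= 0).any() \
                    or not np.isclose(th.sum(), 1.0):
                raise ValueError("theta must be positive on the simplex over "
                                 "the category list")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        S = self.s.shape[0]
        for name in ("f", "m_mc", "m_sc", "n_mc", "n_sc"):
            if getattr(self, name).shape[0] != S:
                raise ValueError("per-sample arrays must share one length")
        if not self.samples:
            self.samples = [f"s{i+1}" for i in range(S)]

    @property
    def K(self) -> int:
        return len(self.categories)

    @property
    def S(self) -> int:
        return self.s.shape[0]

    @property
    def is_null(self) -> bool:
        return bool(np.allclose(self.theta_wt, self.theta_mt))

    @classmethod
    def jregion_matched(cls, null: bool = True, from_posterior: bool = True,
                        phi: float | None = None, s: float = 1e6,
                        f: float = 1e-5, fit_draws: int = 6000,
                        fit_seed: int = 20130) -> "SimConfig":
        """Conditions matched to the six-patient J-region study.

        By default the system parameters are the posterior means from a fit
        to the J-region data (using the documented default bottleneck
        metadata): θ^mt and φ are the posterior means given the MT data, and
        θ^wt is the conjugate posterior mean given the pooled WT counts.
        Under the null θ^wt is set equal to θ^mt.  With
        ``from_posterior=False`` the frequencies fall back to pooled
        empirical fixture counts (pseudocount 1) and φ to 1 unless given.
        Either way this is an approximate replication — the original
        bottleneck metadata and parameter settings were not published — and
        experiment reports flag it as such.
        """
        from .datamodel import default_bottleneck_meta
        from .posterior import run_sampler

        ds = load_fixture_jregion()
        wt = sum(ds.table(t).counts.sum(axis=1) for t in ("WT-MC", "WT-SC"))
        mt = sum(ds.table(t).counts.sum(axis=1) for t in ("MT-MC", "MT-SC"))
        S = ds.table("WT-MC").S
        if from_posterior:
            dsm = ds.with_meta(default_bottleneck_meta(
                ds.table("MT-MC").samples, s=s, f=f))
            post = run_sampler(dsm, draws=fit_draws, burnin=max(1000, fit_draws // 4),
                               seed=fit_seed, ess=False)
            th_mt = post.thetas.mean(axis=0)
            if phi is None:
                phi = float(post.phis.mean())
            K = th_mt.shape[0]
            th_wt = th_mt if null else (wt + 1.0) / (wt.sum() + K)
        else:
            if phi is None:
                phi = 1.0
            if null:
                pooled = wt + mt + 1.0
                th_wt = th_mt = pooled / pooled.sum()
            else:
                th_wt = (wt + 1.0) / (wt + 1.0).sum()
                th_mt = (mt + 1.0) / (mt + 1.0).sum()
        return cls(
            categories=list(ds.categories), theta_wt=th_wt, theta_mt=th_mt,
            phi=phi, s=np.full(S, s), f=np.full(S, f),
            m_mc=ds.table("WT-MC").totals, m_sc=ds.table("WT-SC").totals,
            n_mc=ds.table("MT-MC").totals, n_sc=ds.table("MT-SC").totals,
            samples=list(ds.table("WT-MC").samples),
        )


def _dirichlet_multinomial_rvs(n: int, a: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    pos = a > 0
    out = np.zeros(a.shape[0], dtype=np.int64)
    if n == 0:
        return out
    p = rng.dirichlet(a[pos])
    out[pos] = rng.multinomial(n, p)
    return out


def simulate_dataset(config: SimConfig, rng: np.random.Generator,
                     redraw_log: list | None = None) -> Dataset:
    """Draw one dataset from the hierarchy.

    Samples with Σ_t Z_{i,t} = 0 are redrawn (an empty culture yields no
    sequencing run); the number of redraws can be collected via
    `redraw_log`.
    """
    K, S = config.K, config.S
    X_mc = np.zeros((K, S), dtype=np.int64)
    X_sc = np.zeros((K, S), dtype=np.int64)
    Y_mc = np.zeros((K, S), dtype=np.int64)
    Y_sc = np.zeros((K, S), dtype=np.int64)
    for i in range(S):
        lam = config.s[i] * config.f[i] * config.theta_mt
        if int(config.n_mc[i]) > 0:
            for attempt in range(MAX_REDRAWS + 1):
                Z = rng.poisson(lam)
                if Z.sum() > 0:
                    break
            else:
                raise ConfigurationError(
                    f"sample {config.samples[i]}: s·f so small that no "
                    f"bottleneck survivors were drawn in {MAX_REDRAWS} tries"
                )
            if redraw_log is not None and attempt:
                redraw_log.append((config.samples[i], attempt))
            Y_mc[:, i] = _dirichlet_multinomial_rvs(int(config.n_mc[i]),
                                                    config.phi * Z, rng)
        Y_sc[:, i] = rng.multinomial(int(config.n_sc[i]), config.theta_mt)
        X_mc[:, i] = rng.multinomial(int(config.m_mc[i]), config.theta_wt)
        X_sc[:, i] = rng.multinomial(int(config.m_sc[i]), config.theta_wt)
    cats = list(config.categories)
    names = list(config.samples)
    tables = {
        "WT-MC": CountTable(cats, names, X_mc, "WT-MC"),
        "WT-SC": CountTable(cats, names, X_sc, "WT-SC"),
        "MT-MC": CountTable(cats, names, Y_mc, "MT-MC"),
        "MT-SC": CountTable(cats, names, Y_sc, "MT-SC"),
    }
    meta = {name: SampleMeta(sample=name, s=float(config.s[i]),
                             f=float(config.f[i]))
            for i, name in enumerate(names)}
    return Dataset(tables, meta)


def _run_replicates(config: SimConfig, R: int, draws: int, burnin: int,
                    seed: int) -> np.ndarray:
    root = np.random.SeedSequence(seed)
    pvals = np.empty(R)
    for r, child in enumerate(root.spawn(R)):
        rng = np.random.default_rng(child)
        ds = simulate_dataset(config, rng)
        post = run_sampler(ds, draws=draws, burnin=burnin,
                           seed=int(rng.integers(2**31)))
        pvals[r] = conditional_predictive_pvalue(ds, post, rng).pvalue
    return pvals


def type1_experiment(config: SimConfig, R: int = 200, draws: int = 2000,
                     burnin: int = 1000, seed: int = 0) -> dict:
    """Null-calibration experiment: R conditional predictive p-values on
    null-simulated data, with uniformity summaries."""
    if not config.is_null:
        raise ValueError("type-I experiment needs a null-mode config "
                         "(theta_wt identical to theta_mt)")
    pvals = _run_replicates(config, R, draws, burnin, seed)
    ks = kstest(pvals, "uniform")
    return {
        "pvalues": pvals,
        "R": R,
        "draws": draws,
        "ecdf": {thr: float(np.mean(pvals <= thr)) for thr in (0.01, 0.05, 0.10)},
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def power_experiment(config: SimConfig, R: int = 200, draws: int = 2000,
                     burnin: int = 1000, seed: int = 0) -> dict:
    """Power experiment at thresholds 0.01 and 0.05, with binomial
    standard errors.  Flagged approximate when run from the J-matched
    configuration (see SimConfig.jregion_matched)."""
    pvals = _run_replicates(config, R, draws, burnin, seed)
    out = {"pvalues": pvals, "R": R, "draws": draws,
           "note": "approximate replication: frequency settings estimated "
                   "from pooled fixture counts"}
    for thr in (0.01, 0.05):
        phat = float(np.mean(pvals <= thr))
        out[f"power_{thr}"] = phat
        out[f"se_{thr}"] = float(np.sqrt(phat * (1 - phat) / R))
    return out
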