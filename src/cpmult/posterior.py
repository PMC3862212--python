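"""Metropolis–Hastings block sampler for p(Z, θ, φ | Y = y).

The target conditions on the MT data only: MT-MC counts enter through the
Poisson bottleneck / Dirichlet-multinomial hierarchy, MT-SC counts through
plain multinomials, under a flat Dirichlet(1,…,1) prior on θ and, by
default, a log-uniform prior on φ truncated to [PHI_MIN, PHI_MAX].  A flat
prior on φ is also available, but note that the Dirichlet-multinomial
likelihood tends to a positive constant as φ → ∞ (the latent counts can
absorb the observed proportions), so a flat prior's posterior mass scales
with the truncation ceiling and swamps the φ-identified mode; the
log-uniform default keeps φ data-driven.

Each scan updates Z, θ, and φ in blocks:

* Z: per-coordinate symmetric ±1 random walk.  Moves below the support
  floor (z_{i,t} ≥ 1 wherever y^mc_{i,t} ≥ 1) have zero target density and
  are auto-rejected, which preserves detailed balance coordinatewise.
* θ: Dirichlet(c·θ) proposal with the asymmetric proposal densities in the
  acceptance ratio.  Because Σ_t θ_t = 1, the Poisson means s_i·θ_t·f_i
  contribute Σ_t (Σ_i z_{i,t}) log θ_t to the θ-kernel, so the θ-target is
  Dirichlet-shaped given (Z, SC counts) — used as a test oracle, never as
  the update.
* φ: Gaussian random walk on log φ (with the log-scale Jacobian in the
  ratio when the prior is flat on φ).

The θ and φ blocks repeat a few cheap MH sub-moves per scan to cut
autocorrelation; the Z sweep dominates the scan cost.

Proposal scales adapt toward 20–40% acceptance during burn-in only, then
freeze, so the post-burn-in chain satisfies detailed balance.  The inner
loops are numba-compiled; the per-block Python entry points are thin
wrappers over the same kernels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln as _gammaln

from .datamodel import Dataset, pool_wildtype
from .distributions import dirichlet_multinomial_logpmf, multinomial_logpmf

PHI_MAX = 1e6
PHI_MIN = 1e-4
THETA_PROP_SCALE = 500.0  # per category: proposal concentration c = scale·K
PHI_STEP = 0.3            # initial log-scale random-walk step
ACC_LOW, ACC_HIGH = 0.20, 0.40
THETA_SUBMOVES = 5        # MH sub-moves per θ block
PHI_SUBMOVES = 2          # MH sub-moves per φ block
SEED_MOD = 2**31


class ConfigurationError(ValueError):
    """Missing metadata or invalid sampler configuration."""


# ---------------------------------------------------------------------------
# State containers

@dataclass
class LatentState:
    """Current sampler state: latent survivors Z (one row per MT-MC sample),
    type frequencies θ, growth-overdispersion φ."""

    Z: np.ndarray      # (S_mc, K) int64
    theta: np.ndarray  # (K,) float, strictly positive, sums to 1
    phi: float

    def validate(self, y_mc: np.ndarray | None = None) -> None:
        if (self.Z < 0).any():
            raise ValueError("latent counts must be non-negative")
        if y_mc is not None and ((self.Z == 0) & (y_mc > 0)).any():
            raise ValueError("Z must be ≥ 1 wherever y^mc ≥ 1")
        if (self.theta <= 0).any() or not np.isclose(self.theta.sum(), 1.0):
            raise ValueError("theta must be strictly positive on the simplex")
        if not (0 < self.phi):
            raise ValueError("phi must be positive")


@dataclass
class PosteriorDraws:
    """Saved MCMC output."""

    thetas: np.ndarray            # (G, K)
    phis: np.ndarray              # (G,)
    seed: int
    burnin: int
    thin: int = 1
    Z_draws: np.ndarray | None = None   # optional (G_thinned, S_mc, K)
    acceptance: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def G(self) -> int:
        return self.thetas.shape[0]

    @property
    def K(self) -> int:
        return self.thetas.shape[1]

    def to_tsv(self, path) -> None:
        """One row per draw: φ then θ_1..θ_K."""
        out = np.column_stack([self.phis, self.thetas])
        header = "phi\t" + "\t".join(f"theta_{k}" for k in range(self.K))
        np.savetxt(path, out, delimiter="\t", header=header, comments="")


# ---------------------------------------------------------------------------
# numba kernels (shared by run_sampler and the per-block entry points)

@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _lgam(x):
    return math.lgamma(x)


@njit(cache=True)
def _z_sweep(z, floor, y_mc, n_mc, sf, theta, phi):
    """One symmetric ±1 Metropolis sweep over every (i,t).  Returns
    (accepted, proposed)."""
    S, K = z.shape
    acc = 0
    for i in range(S):
        Zi = 0
        for t in range(K):
            Zi += z[i, t]
        n = n_mc[i]
        for t in range(K):
            zt = z[i, t]
            up = np.random.random() < 0.5
            znew = zt + 1 if up else zt - 1
            if znew < floor[i, t]:
                continue
            lam = sf[i] * theta[t]
            if up:
                d = np.log(lam) - np.log(zt + 1.0)
            else:
                d = np.log(float(zt)) - np.log(lam)
            Znew = Zi + 1 if up else Zi - 1
            y = y_mc[i, t]
            if n > 0:
                # Γ(φZ)/Γ(n+φZ) factor; Z ≥ 1 is guaranteed when n > 0
                d += _lgam(phi * Znew) - _lgam(phi * Zi)
                d -= _lgam(n + phi * Znew) - _lgam(n + phi * Zi)
                # per-category Γ(φz+y)/Γ(φz); terms with z=0 (then y=0) are 1
                told = _lgam(phi * zt + y) - _lgam(phi * zt) if zt > 0 else 0.0
                tnew = _lgam(phi * znew + y) - _lgam(phi * znew) if znew > 0 else 0.0
                d += tnew - told
            if d >= 0.0 or np.log(np.random.random()) < d:
                z[i, t] = znew
                Zi = Znew
                acc += 1
    return acc, S * K


@njit(cache=True)
def _theta_update(theta, a, c):
    """Dirichlet(c·θ) proposal for θ with target ∝ Π θ_t^{a_t}.  Returns 1
    if accepted (θ modified in place)."""
    K = theta.shape[0]
    if K == 1:
        return 1
    prop = np.empty(K)
    tot = 0.0
    for t in range(K):
        g = np.random.gamma(c * theta[t], 1.0)
        prop[t] = g
        tot += g
    if tot <= 0.0:
        return 0
    for t in range(K):
        prop[t] /= tot
        if prop[t] <= 0.0:
            return 0
    d = 0.0
    for t in range(K):
        lo, ln = np.log(theta[t]), np.log(prop[t])
        d += a[t] * (ln - lo)
        # q(θ|θ') - q(θ'|θ): Dirichlet log-densities with parameters c·θ', c·θ
        d += (c * prop[t] - 1.0) * lo - _lgam(c * prop[t])
        d -= (c * theta[t] - 1.0) * ln - _lgam(c * theta[t])
    if d >= 0.0 or np.log(np.random.random()) < d:
        for t in range(K):
            theta[t] = prop[t]
        return 1
    return 0


@njit(cache=True)
def _dm_loglik_phi(z, y_mc, n_mc, phi):
    """Σ_i log DM(y^mc_i; n_i, φ·z_i), dropping y-only constants that cancel
    in φ ratios."""
    S, K = z.shape
    ll = 0.0
    for i in range(S):
        n = n_mc[i]
        if n == 0:
            continue
        Zi = 0
        for t in range(K):
            Zi += z[i, t]
        ll += _lgam(phi * Zi) - _lgam(n + phi * Zi)
        for t in range(K):
            if z[i, t] > 0:
                ll += _lgam(phi * z[i, t] + y_mc[i, t]) - _lgam(phi * z[i, t])
    return ll


@njit(cache=True)
def _phi_update(phi, sigma, z, y_mc, n_mc, phi_min, phi_max, flat_prior):
    """Log-scale Gaussian random walk for φ.  Under the default
    log-uniform prior the log-scale target needs no Jacobian; under the
    flat-on-φ prior the Jacobian log φ' − log φ enters the ratio.  Returns
    (new_phi, accepted)."""
    prop = phi * np.exp(sigma * np.random.normal())
    if prop > phi_max or prop < phi_min:
        return phi, 0
    d = np.log(prop) - np.log(phi) if flat_prior else 0.0
    if y_mc.shape[0] > 0:
        d += _dm_loglik_phi(z, y_mc, n_mc, prop) - _dm_loglik_phi(z, y_mc, n_mc, phi)
    if d >= 0.0 or np.log(np.random.random()) < d:
        return prop, 1
    return phi, 0


@njit(cache=True)
def _run_chain(y_mc, n_mc, sf, a_base, z0, theta0, phi0,
               burnin, G, thin, c0, sigma0, phi_min, phi_max, flat_prior,
               adapt, fix_phi, save_z):
    S, K = y_mc.shape
    z = z0.copy()
    floor = np.zeros((S, K), dtype=np.int64)
    for i in range(S):
        for t in range(K):
            if y_mc[i, t] > 0:
                floor[i, t] = 1
    theta = theta0.copy()
    phi = phi0
    c = c0
    sigma = sigma0
    thetas = np.empty((G, K))
    phis = np.empty(G)
    zs = np.empty((G if save_z else 0, S, K), dtype=np.int64)
    acc = np.zeros(3)      # post-burn-in acceptance counts: Z, θ, φ
    prop = np.zeros(3)
    win = np.zeros(2)      # burn-in adaptation window counts: θ, φ
    winN = 0
    a = np.empty(K)
    nscan = burnin + G * thin
    for scan in range(nscan):
        az, pz = _z_sweep(z, floor, y_mc, n_mc, sf, theta, phi)
        for t in range(K):
            s = a_base[t]
            for i in range(S):
                s += z[i, t]
            a[t] = s
        # the θ and φ blocks repeat cheap MH sub-moves to cut autocorrelation;
        # the Z sweep dominates the scan cost
        at = 0
        for _ in range(THETA_SUBMOVES):
            at += _theta_update(theta, a, c)
        if fix_phi:
            ap = PHI_SUBMOVES
        else:
            ap = 0
            for _ in range(PHI_SUBMOVES):
                phi, ok = _phi_update(phi, sigma, z, y_mc, n_mc, phi_min,
                                      phi_max, flat_prior)
                ap += ok
        if scan < burnin:
            if adapt:
                win[0] += at
                win[1] += ap
                winN += 1
                if winN == 50:
                    r0 = win[0] / (50.0 * THETA_SUBMOVES)
                    if r0 < ACC_LOW:
                        c *= 1.5   # smaller steps: higher concentration
                    elif r0 > ACC_HIGH:
                        c /= 1.5
                    r1 = win[1] / (50.0 * PHI_SUBMOVES)
                    if r1 < ACC_LOW:
                        sigma /= 1.5
                    elif r1 > ACC_HIGH:
                        sigma *= 1.5
                    win[0] = 0.0
                    win[1] = 0.0
                    winN = 0
        else:
            acc[0] += az
            prop[0] += pz
            acc[1] += at
            prop[1] += THETA_SUBMOVES
            acc[2] += ap
            prop[2] += PHI_SUBMOVES
            k = scan - burnin
            if k % thin == 0:
                g = k // thin
                if g < G:
                    for t in range(K):
                        thetas[g, t] = theta[t]
                    phis[g] = phi
                    if save_z:
                        for i in range(S):
                            for t in range(K):
                                zs[g, i, t] = z[i, t]
    return thetas, phis, zs, acc, prop, c, sigma


# ---------------------------------------------------------------------------
# Dataset packing

def _pack(dataset: Dataset, components=("mt_mc", "mt_sc")):
    """Extract sampler arrays from a Dataset.

    components ⊆ {"mt_mc", "mt_sc", "wt"} selects which likelihood pieces
    enter the target ("wt" adds the pooled WT multinomial, used by the LR
    baseline's null fit).
    """
    K = dataset.K
    y_mc = np.zeros((0, K), dtype=np.int64)
    sf = np.zeros(0)
    if "mt_mc" in components and dataset.table("MT-MC") is not None:
        tab = dataset.table("MT-MC")
        keep = [j for j in range(tab.S) if tab.counts[:, j].sum() > 0]
        y_mc = tab.counts[:, keep].T.copy()
        sfs = []
        for j in keep:
            name = tab.samples[j]
            if name not in dataset.meta:
                raise ConfigurationError(
                    f"sample {name!r} has MT-MC counts but no metadata (s_i, f_i)"
                )
            sfs.append(dataset.meta[name].sf)
        sf = np.asarray(sfs, dtype=float)
        if (sf <= 0).any():
            raise ConfigurationError("s_i · f_i must be positive for MT-MC samples")
    a_base = np.zeros(K)
    if "mt_sc" in components and dataset.table("MT-SC") is not None:
        a_base += dataset.table("MT-SC").counts.sum(axis=1)
    if "wt" in components:
        x, _ = pool_wildtype(dataset)
        a_base += x
    n_mc = y_mc.sum(axis=1)
    return y_mc, n_mc, sf, a_base


def _initial_state(y_mc, n_mc, sf, a_base) -> LatentState:
    K = a_base.shape[0]
    pooled = a_base + y_mc.sum(axis=0) + 1.0  # pseudocount 1
    theta = pooled / pooled.sum()
    S = y_mc.shape[0]
    z = np.zeros((S, K), dtype=np.int64)
    for i in range(S):
        z[i] = np.maximum((y_mc[i] > 0).astype(np.int64),
                          np.round(sf[i] * theta).astype(np.int64))
    return LatentState(Z=z, theta=theta, phi=1.0)


# ---------------------------------------------------------------------------
# Public operations

def log_joint(state: LatentState, dataset: Dataset,
              components=("mt_mc", "mt_sc")) -> float:
    """Unnormalized log posterior density of (Z, θ, φ) given the MT data.

    Σ_i [ Σ_t log Poisson(z_{i,t}; s_i θ_t f_i) + log DM(y^mc_i; n^mc_i, φ·z_i)
          + log Mult(y^sc_i; n^sc_i, θ) ] + log prior.  States violating the
    Z support constraint get -inf rather than an exception.
    """
    y_mc, n_mc, sf, _ = _pack(dataset, components)
    theta = np.asarray(state.theta, dtype=float)
    if (theta <= 0).any():
        return float("-inf")
    if state.phi <= 0 or state.phi > PHI_MAX:
        return float("-inf")
    total = 0.0  # flat Dirichlet(1,..,1) prior on θ and flat prior on φ add 0
    for i in range(y_mc.shape[0]):
        lam = sf[i] * theta
        z = np.asarray(state.Z[i], dtype=float)
        total += float((z * np.log(lam) - lam - _gammaln(z + 1)).sum())
        dm = dirichlet_multinomial_logpmf(y_mc[i], int(n_mc[i]), state.phi * state.Z[i])
        if not np.isfinite(dm):
            return float("-inf")
        total += dm
    if "mt_sc" in components and dataset.table("MT-SC") is not None:
        sc = dataset.table("MT-SC")
        for j in range(sc.S):
            col = sc.counts[:, j]
            total += multinomial_logpmf(col, int(col.sum()), theta)
    if "wt" in components:
        x, m = pool_wildtype(dataset)
        total += multinomial_logpmf(x, m, theta)
    return total


def _block_seed(rng: np.random.Generator) -> None:
    _seed(int(rng.integers(SEED_MOD)))


def update_Z_block(state: LatentState, dataset: Dataset,
                   rng: np.random.Generator) -> LatentState:
    """One ±1 Metropolis sweep over all latent coordinates (i, t)."""
    y_mc, n_mc, sf, _ = _pack(dataset)
    floor = (y_mc > 0).astype(np.int64)
    z = state.Z.copy()
    _block_seed(rng)
    _z_sweep(z, floor, y_mc, n_mc, sf,
             np.asarray(state.theta, dtype=float), float(state.phi))
    return LatentState(Z=z, theta=state.theta.copy(), phi=state.phi)


def update_theta_block(state: LatentState, dataset: Dataset,
                       rng: np.random.Generator,
                       c: float | None = None,
                       components=("mt_mc", "mt_sc")) -> LatentState:
    """Metropolis–Hastings update of θ with a Dirichlet(c·θ) proposal."""
    _, _, _, a_base = _pack(dataset, components)
    a = a_base + state.Z.sum(axis=0)
    theta = np.asarray(state.theta, dtype=float).copy()
    if c is None:
        c = THETA_PROP_SCALE * theta.shape[0]
    _block_seed(rng)
    _theta_update(theta, a.astype(float), float(c))
    return LatentState(Z=state.Z.copy(), theta=theta, phi=state.phi)


def update_phi_block(state: LatentState, dataset: Dataset,
                     rng: np.random.Generator,
                     sigma: float = PHI_STEP,
                     phi_min: float = PHI_MIN,
                     phi_max: float = PHI_MAX,
                     phi_prior: str = "log-uniform") -> LatentState:
    """Log-scale random-walk update of φ, truncated to [phi_min, phi_max]."""
    y_mc, n_mc, _, _ = _pack(dataset)
    _block_seed(rng)
    phi, _ = _phi_update(float(state.phi), float(sigma), state.Z, y_mc, n_mc,
                         float(phi_min), float(phi_max), phi_prior == "flat")
    return LatentState(Z=state.Z.copy(), theta=state.theta.copy(), phi=phi)


def run_sampler(dataset: Dataset, draws: int = 10_000, burnin: int = 2_000,
                thin: int = 1, seed: int = 0, save_z: bool = False,
                components=("mt_mc", "mt_sc"), fix_phi: float | None = None,
                phi_prior: str = "log-uniform", adapt: bool = True,
                ess: bool = True) -> PosteriorDraws:
    """Run the block Metropolis–Hastings sampler and save `draws` states.

    Each scan is one Z sweep, one θ block, one φ block (in that order).
    Proposal scales adapt during burn-in only.  With `fix_phi` set, φ is held
    constant (used by diagnostics and the simulator-consistency check).
    """
    y_mc, n_mc, sf, a_base = _pack(dataset, components)
    st = _initial_state(y_mc, n_mc, sf, a_base)
    if fix_phi is not None:
        st.phi = float(fix_phi)
    if phi_prior not in ("log-uniform", "flat"):
        raise ConfigurationError("phi_prior must be 'log-uniform' or 'flat'")
    _seed(int(seed) % SEED_MOD)
    thetas, phis, zs, acc, prop, c, sigma = _run_chain(
        y_mc, n_mc, sf, a_base, st.Z, st.theta, float(st.phi),
        int(burnin), int(draws), int(thin),
        THETA_PROP_SCALE * dataset.K, PHI_STEP, PHI_MIN, PHI_MAX,
        phi_prior == "flat", adapt, fix_phi is not None, save_z)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = {name: float(acc[k] / prop[k]) if prop[k] else float("nan")
                 for k, name in enumerate(("Z", "theta", "phi"))}
    diag: dict = {"theta_prop_concentration": float(c), "phi_step": float(sigma),
                  "phi_identified": bool(y_mc.shape[0] > 0)}
    if ess:
        try:
            import arviz as az
            idx = np.linspace(0, thetas.shape[1] - 1, min(3, thetas.shape[1])).astype(int)
            diag["ess_theta"] = {int(t): float(az.ess(np.asarray(thetas[:, t])))
                                 for t in idx}
            if fix_phi is None and y_mc.shape[0] > 0:
                diag["ess_phi"] = float(az.ess(np.asarray(phis)))
        except Exception:  # diagnostics must never fail a run
            pass
    return PosteriorDraws(thetas=thetas, phis=phis, seed=int(seed),
                          burnin=int(burnin), thin=int(thin),
                          Z_draws=zs if save_z else None,
                          acceptance=rates, diagnostics=diag)
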