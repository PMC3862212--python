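import numpy as np
import pytest

from cpmult.datamodel import (CountTable, Dataset, SampleMeta,
                              default_bottleneck_meta)
from cpmult.distributions import (dirichlet_multinomial_logpmf,
                                  multinomial_logpmf)
from cpmult.posterior import (ConfigurationError, LatentState, log_joint,
                              run_sampler, update_phi_block,
                              update_theta_block, update_Z_block, _seed,
                              _theta_update, _z_sweep)


def _mini_dataset(y_mc, y_sc, s=1e6, f=1e-5, cats=None):
    y_mc = np.atleast_2d(np.asarray(y_mc))
    y_sc = np.atleast_2d(np.asarray(y_sc))
    K = y_mc.shape[1]
    cats = cats or [f"c{t}" for t in range(K)]
    names = [f"s{i}" for i in range(y_mc.shape[0])]
    tables = {
        "MT-MC": CountTable(cats, names, y_mc.T, "MT-MC"),
        "MT-SC": CountTable(cats, names, y_sc.T, "MT-SC"),
    }
    meta = {n: SampleMeta(sample=n, s=s, f=f) for n in names}
    return Dataset(tables, meta)


def _sc_only_dataset(y_sc):
    y_sc = np.atleast_2d(np.asarray(y_sc))
    K = y_sc.shape[1]
    cats = [f"c{t}" for t in range(K)]
    names = [f"s{i}" for i in range(y_sc.shape[0])]
    return Dataset({"MT-SC": CountTable(cats, names, y_sc.T, "MT-SC")})


class TestLogJoint:
    def test_composes_from_kernels(self):
        ds = _mini_dataset([[3, 2]], [[1, 4]], s=1e6, f=2e-6)
        st = LatentState(Z=np.array([[2, 1]]), theta=np.array([0.4, 0.6]),
                         phi=1.5)
        lam = 2.0 * st.theta
        import math
        pois = sum(z * np.log(l) - l - math.lgamma(z + 1)
                   for z, l in zip([2, 1], lam))
        expected = (pois
                    + dirichlet_multinomial_logpmf([3, 2], 5, st.phi * st.Z[0])
                    + multinomial_logpmf([1, 4], 5, st.theta))
        assert log_joint(st, ds) == pytest.approx(expected)

    def test_support_violation_is_minus_inf(self):
        ds = _mini_dataset([[1, 0]], [[0, 0]])
        st = LatentState(Z=np.array([[0, 1]]), theta=np.array([0.5, 0.5]),
                         phi=1.0)
        assert log_joint(st, ds) == -np.inf

    def test_reduces_to_multinomial_without_mc(self):
        ds = _sc_only_dataset([[2, 3]])
        st = LatentState(Z=np.zeros((0, 2), dtype=np.int64),
                         theta=np.array([0.3, 0.7]), phi=1.0)
        assert log_joint(st, ds) == pytest.approx(
            multinomial_logpmf([2, 3], 5, [0.3, 0.7]))


class TestZBlock:
    def test_support_floor_never_crossed(self):
        ds = _mini_dataset([[3, 0]], [[0, 0]], f=1e-6)
        st = LatentState(Z=np.array([[1, 0]]), theta=np.array([0.5, 0.5]),
                         phi=1e8)
        rng = np.random.default_rng(0)
        for _ in range(200):
            st = update_Z_block(st, ds, rng)
            assert st.Z[0, 0] >= 1 and st.Z[0, 1] >= 0

    def test_truncated_poisson_stationary_law(self):
        """Single category, huge φ: the DM factor is constant, so Z is a
        Poisson(s·θ·f) random variable truncated to z ≥ 1."""
        lam = 2.5
        ds = _mini_dataset([[4]], [[0]], s=1e6, f=lam * 1e-6)
        theta = np.array([1.0])
        _seed(123)
        z = np.ones((1, 1), dtype=np.int64)
        floor = np.ones((1, 1), dtype=np.int64)
        samples = []
        for it in range(40_000):
            _z_sweep(z, floor, np.array([[4]]), np.array([4]),
                     np.array([lam]), theta, 1e10)
            if it >= 1000:
                samples.append(z[0, 0])
        got = np.mean(samples)
        want = lam / (1 - np.exp(-lam))  # truncated-Poisson mean
        assert got == pytest.approx(want, rel=0.03)

    def test_deterministic_given_seed(self, jdata_meta):
        a = run_sampler(jdata_meta, draws=50, burnin=20, seed=9, ess=False)
        b = run_sampler(jdata_meta, draws=50, burnin=20, seed=9, ess=False)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.phis, b.phis)


class TestThetaBlock:
    def test_conjugate_dirichlet_oracle(self):
        """Without the MC branch the θ posterior is Dirichlet(1 + Σ y^sc)."""
        counts = np.array([7, 2, 11])
        ds = _sc_only_dataset([counts])
        post = run_sampler(ds, draws=100_000, burnin=2_000, seed=4, ess=False)
        want = (1.0 + counts) / (3 + counts.sum())
        assert post.thetas.mean(axis=0) == pytest.approx(want, rel=0.01)
        a0 = 3 + counts.sum()
        want_var = want * (1 - want) / (a0 + 1)
        assert post.thetas.var(axis=0) == pytest.approx(want_var, rel=0.06)

    def test_single_category_is_noop(self):
        _seed(0)
        theta = np.array([1.0])
        assert _theta_update(theta, np.array([5.0]), 100.0) == 1
        assert theta[0] == 1.0

    def test_acceptance_rate_interior(self, jdata_meta):
        post = run_sampler(jdata_meta, draws=1000, burnin=500, seed=2,
                           ess=False)
        assert 0.0 < post.acceptance["theta"] < 1.0


class TestPhiBlock:
    def test_flat_prior_jacobian(self):
        """With no MC data and a flat-on-φ target restricted to [1, 3], the
        log-scale walk (Jacobian included) must leave φ uniform on [1, 3]."""
        ds = _sc_only_dataset([[1, 1]])
        st = LatentState(Z=np.zeros((0, 2), dtype=np.int64),
                         theta=np.array([0.5, 0.5]), phi=2.0)
        rng = np.random.default_rng(8)
        vals = []
        for it in range(30_000):
            st = update_phi_block(st, ds, rng, sigma=0.4, phi_min=1.0,
                                  phi_max=3.0, phi_prior="flat")
            if it >= 500:
                vals.append(st.phi)
        vals = np.asarray(vals)
        assert vals.mean() == pytest.approx(2.0, abs=0.03)
        assert np.mean(vals < 2.0) == pytest.approx(0.5, abs=0.03)

    def test_unidentified_without_mc_flagged(self):
        ds = _sc_only_dataset([[3, 4]])
        post = run_sampler(ds, draws=500, burnin=100, seed=1, ess=False)
        assert post.diagnostics["phi_identified"] is False

    def test_phi_recovery_coverage(self):
        """90% posterior intervals for φ cover the generating value in the
        vast majority of replications (K=5, 6 samples, n=100)."""
        from cpmult.simulate import SimConfig, simulate_dataset
        theta = np.full(5, 0.2)
        cfg = SimConfig(categories=list("abcde"), theta_wt=theta,
                        theta_mt=theta, phi=1.0, s=np.full(6, 1e6),
                        f=np.full(6, 1e-5), m_mc=np.full(6, 0),
                        m_sc=np.full(6, 0), n_mc=np.full(6, 100),
                        n_sc=np.full(6, 100))
        cover = 0
        root = np.random.SeedSequence(42)
        R = 50
        for child in root.spawn(R):
            rng = np.random.default_rng(child)
            ds = simulate_dataset(cfg, rng)
            post = run_sampler(ds, draws=1500, burnin=800,
                               seed=int(rng.integers(2**31)), ess=False)
            lo, hi = np.quantile(post.phis, [0.05, 0.95])
            cover += (lo <= 1.0 <= hi)
        assert cover >= 0.8 * R


class TestRunSampler:
    def test_missing_metadata_is_configuration_error(self, jdata):
        with pytest.raises(ConfigurationError):
            run_sampler(jdata, draws=10, burnin=5, seed=0)

    def test_saved_states_valid(self, jdata_meta):
        post = run_sampler(jdata_meta, draws=300, burnin=200, seed=5,
                           save_z=True, ess=False)
        assert post.G == 300
        assert np.allclose(post.thetas.sum(axis=1), 1.0)
        assert (post.thetas > 0).all()
        assert (post.phis > 0).all()
        y_mc = jdata_meta.table("MT-MC").counts.T
        assert ((post.Z_draws >= 1) | (y_mc[None] == 0)).all()

    def test_theta_recovery_improves_with_depth(self):
        """Posterior θ means approach the generating values as sequencing
        depth grows."""
        from cpmult.simulate import SimConfig, simulate_dataset
        theta = np.array([0.5, 0.3, 0.15, 0.05])
        err = {}
        for n in (50, 500):
            cfg = SimConfig(categories=list("abcd"), theta_wt=theta,
                            theta_mt=theta, phi=1.0, s=np.full(6, 1e6),
                            f=np.full(6, 1e-5), m_mc=np.full(6, 0),
                            m_sc=np.full(6, 0), n_mc=np.full(6, n),
                            n_sc=np.full(6, n))
            devs = []
            root = np.random.SeedSequence(n)
            for child in root.spawn(8):
                rng = np.random.default_rng(child)
                ds = simulate_dataset(cfg, rng)
                post = run_sampler(ds, draws=1500, burnin=800,
                                   seed=int(rng.integers(2**31)), ess=False)
                devs.append(np.abs(post.thetas.mean(0) - theta).sum())
            err[n] = np.mean(devs)
        assert err[500] < err[50]

    def test_geweke_forward_vs_successive_conditional(self):
        """Forward simulation of (θ, Z, Y) matches the sampler's stationary
        law on a tiny instance (K=2, one sample, φ fixed)."""
        K, sf, n_mc, n_sc, phi = 2, 5.0, 5, 5, 1.0
        rng = np.random.default_rng(0)

        def dm_rvs(n, a):
            pos = a > 0
            out = np.zeros(K, dtype=np.int64)
            if n and pos.any():
                out[pos] = rng.multinomial(n, rng.dirichlet(a[pos]))
            return out

        def forward():
            while True:
                th = rng.dirichlet(np.ones(K))
                Z = rng.poisson(sf * th)
                if Z.sum() > 0:
                    break
            return th, Z, dm_rvs(n_mc, phi * Z), rng.multinomial(n_sc, th)

        N, M = 12_000, 15
        F = [forward() for _ in range(N)]
        th_f = np.array([f[0][0] for f in F])
        Z_f = np.array([f[1] for f in F], dtype=float)

        _seed(321)
        th, Z, ymc, ysc = forward()
        ths, Zs = [], []
        for _ in range(N):
            floor = (ymc > 0).astype(np.int64).reshape(1, K)
            z2 = Z.reshape(1, K).astype(np.int64).copy()
            for _ in range(M):
                _z_sweep(z2, floor, ymc.reshape(1, K),
                         np.array([int(ymc.sum())]), np.array([sf]), th, phi)
                _theta_update(th, z2[0] + ysc + 0.0, 50.0)
            Z = z2[0]
            ymc = dm_rvs(n_mc, phi * Z)
            ysc = rng.multinomial(n_sc, th)
            ths.append(th[0])
            Zs.append(Z.copy())
        ths = np.array(ths)
        Zs = np.array(Zs, dtype=float)

        def zscore(a, b):
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            return abs(a.mean() - b.mean()) / se

        # generous thresholds: the chain is autocorrelated
        assert zscore(th_f, ths) < 5
        assert zscore(th_f**2, ths**2) < 5
        assert zscore(Z_f[:, 0], Zs[:, 0]) < 5
        assert zscore(Z_f.sum(1)**2, Zs.sum(1)**2) < 5

    def test_tsv_serialization(self, jdata_meta, tmp_path):
        post = run_sampler(jdata_meta, draws=20, burnin=10, seed=0, ess=False)
        p = tmp_path / "draws.tsv"
        post.to_tsv(p)
        back = np.loadtxt(p, delimiter="\t", skiprows=1)
        assert back.shape == (20, 14)
        assert np.allclose(back[:, 0], post.phis)
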