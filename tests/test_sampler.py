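import numpy as np
import pytest
from scipy import stats

from dynb.model_core import (
    KernelHyperparams,
    default_priors,
    gp_covariance,
    joint_log_likelihood,
    nb_log_pmf,
    timescale_grid,
)
from dynb.normalization import VarianceFunction
from dynb.sampler import GeneData, MHConfig, k_move, psrf, run_chains, run_mh

VF = VarianceFunction(0.0, 1.0, 0.05)


class TestKMove:
    def test_move_frequencies_are_one_third(self):
        grid = timescale_grid(72.0)
        rng = np.random.default_rng(0)
        moves = np.array([k_move(0.0, grid, rng) for _ in range(100_000)])
        for target in (-4.0, 0.0, 4.0):
            assert np.mean(moves == target) == pytest.approx(1 / 3, abs=0.01)

    def test_off_grid_current_delta_rejected(self):
        grid = timescale_grid(72.0)
        with pytest.raises(ValueError, match="not on the grid"):
            k_move(2.0, grid, np.random.default_rng(0))


class TestPriorOnlySampling:
    """With a constant likelihood the chain must reproduce the priors."""

    def test_theta2_recovers_uniform(self):
        d = GeneData(counts=[[10, 20, 30]], size_factors=[[1, 1, 1]],
                     times=[0, 12, 24], replicate_labels=["r1"])
        pri = default_priors(np.array([10, 20, 30]))
        cfg = MHConfig(n_iter=50_000, burn_in=2_000, n_chains=1, seed=9,
                       theta2_proposal_sd=0.25, prior_only=True)
        ch = run_mh(d, pri, VF, cfg)
        t2 = ch.post_burn_in(ch.theta2)
        ks = stats.kstest(t2, lambda x: np.clip((x - 0.5) / 0.5, 0, 1)).statistic
        assert ks < 0.05

    def test_delta_recovers_symmetric_prior(self):
        grid = timescale_grid(24.0, 8.0, 4.0)
        d = GeneData(counts=[[5, 10], [6, 11]], size_factors=np.ones((2, 2)),
                     times=[0, 24], replicate_labels=["r1", "r2"],
                     reference=0, timescale=True)
        pri = default_priors(np.array([5, 10, 6, 11]), grid=grid)
        cfg = MHConfig(n_iter=60_000, burn_in=5_000, n_chains=1, seed=9,
                       theta2_proposal_sd=0.25, prior_only=True)
        ch = run_mh(d, pri, VF, cfg, grid=grid)
        deltas = ch.post_burn_in(ch.deltas[:, 1])
        emp = np.array([np.mean(np.isclose(deltas, dd)) for dd in grid.deltas])
        tv = 0.5 * np.sum(np.abs(emp - pri.k_prior_mass))
        assert tv < 0.05

    def test_reference_replicate_never_moves(self):
        grid = timescale_grid(24.0, 8.0, 4.0)
        d = GeneData(counts=[[5, 10], [6, 11]], size_factors=np.ones((2, 2)),
                     times=[0, 24], replicate_labels=["r1", "r2"],
                     reference=0, timescale=True)
        pri = default_priors(np.array([5, 10, 6, 11]), grid=grid)
        cfg = MHConfig(n_iter=5_000, burn_in=0, n_chains=1, seed=9,
                       prior_only=True)
        ch = run_mh(d, pri, VF, cfg, grid=grid)
        assert np.all(ch.deltas[:, 0] == 0.0)
        # and the free replicate stays within the grid bounds
        assert np.all(np.abs(ch.deltas[:, 1]) <= 8.0)


class TestChainContracts:
    def _small_fit(self, seed=11, **cfg_kw):
        rng = np.random.default_rng(1)
        y = np.rint(rng.uniform(20, 300, size=(2, 3)))
        d = GeneData(counts=y, size_factors=np.ones((2, 3)), times=[0, 12, 24],
                     replicate_labels=["r1", "r2"])
        pri = default_priors(y)
        cfg = MHConfig(n_iter=2_000, burn_in=500, n_chains=1, seed=seed, **cfg_kw)
        return d, pri, run_mh(d, pri, VF, cfg)

    def test_seeded_runs_are_bit_reproducible(self):
        _, _, ch1 = self._small_fit(seed=13)
        _, _, ch2 = self._small_fit(seed=13)
        np.testing.assert_array_equal(ch1.f, ch2.f)
        np.testing.assert_array_equal(ch1.theta2, ch2.theta2)
        np.testing.assert_array_equal(ch1.loglik, ch2.loglik)

    def test_stored_logliks_match_recomputation(self):
        d, pri, ch = self._small_fit()
        for it in range(0, ch.n_iter, 197):
            ll = joint_log_likelihood(
                d.counts, ch.f[it], d.times, [1.0, 1.0], d.size_factors, VF,
                eval_times=ch.eval_times,
            )
            assert ll == pytest.approx(ch.loglik[it], abs=1e-10)

    def test_theta2_stays_in_prior_support(self):
        _, _, ch = self._small_fit()
        assert np.all((ch.theta2 >= 0.5) & (ch.theta2 <= 1.0))

    def test_sample_count_equals_n_iter(self):
        _, _, ch = self._small_fit()
        assert ch.f.shape[0] == ch.n_iter == 2_000


class TestDetailedBalance:
    def test_matches_brute_force_posterior_2d(self):
        """On a 2-point problem the MH stationary law matches quadrature."""
        y = np.array([[30.0, 120.0]])
        d = GeneData(counts=y, size_factors=np.ones((1, 2)), times=[0.0, 24.0],
                     replicate_labels=["r1"])
        pri = default_priors(y)
        cfg = MHConfig(n_iter=200_000, burn_in=10_000, n_chains=1, seed=17)
        ch = run_mh(d, pri, VF, cfg)
        f = ch.post_burn_in(ch.f)

        K = gp_covariance(np.array([0.0, 24.0]),
                          KernelHyperparams(pri.gp.sigma1, pri.gp.sigma2))
        Kinv = np.linalg.inv(K)
        m = pri.gp.m
        g1 = np.linspace(1, 120, 160)
        g2 = np.linspace(40, 260, 160)
        F1, F2 = np.meshgrid(g1, g2, indexing="ij")
        dev = np.stack([F1 - m, F2 - m], -1)
        quad = np.einsum("...i,ij,...j->...", dev, Kinv, dev)
        lp = (nb_log_pmf(30.0, F1, VF(F1)) + nb_log_pmf(120.0, F2, VF(F2))
              - 0.5 * quad)
        P = np.exp(lp - lp.max())
        P /= P.sum()

        bins1 = np.linspace(g1[0], g1[-1], 7)
        bins2 = np.linspace(g2[0], g2[-1], 7)
        H, _, _ = np.histogram2d(f[:, 0], f[:, 1], bins=[bins1, bins2])
        H /= H.sum()
        i1 = np.clip(np.digitize(g1, bins1) - 1, 0, 5)
        i2 = np.clip(np.digitize(g2, bins2) - 1, 0, 5)
        # aggregate brute-force mass into the same coarse bins
        Pb = np.zeros((6, 6))
        for a in range(g1.size):
            for b in range(g2.size):
                Pb[i1[a], i2[b]] += P[a, b]
        tv = 0.5 * np.abs(H - Pb).sum()
        assert tv < 0.05

    def test_timescale_posterior_matches_enumeration(self):
        """2 replicates, 2 timepoints, 3 shifts: exact MC-integrated truth."""
        from scipy.special import logsumexp

        grid = timescale_grid(12.0, 4.0, 4.0)
        y = np.array([[40.0, 200.0], [40.0, 150.0]])
        d = GeneData(counts=y, size_factors=np.ones((2, 2)), times=[0.0, 12.0],
                     replicate_labels=["r1", "r2"], reference=0, timescale=True)
        pri = default_priors(y, grid=grid)
        from dynb.sampler import _eval_grid

        ev, imap = _eval_grid(d, grid)
        K = gp_covariance(ev, KernelHyperparams(pri.gp.sigma1, pri.gp.sigma2))
        L = np.linalg.cholesky(K)
        rng = np.random.default_rng(99)
        n_mc = 4_000_000
        F = pri.gp.m + rng.standard_normal((n_mc, ev.size)) @ L.T
        logev = []
        for gi in range(grid.n):
            used = np.unique(np.concatenate([imap[1], imap[gi]]))
            ok = np.all(F[:, used] > 0, axis=1)
            lp = np.full(n_mc, -np.inf)
            mus = [F[ok, imap[1][0]], F[ok, imap[1][1]],
                   F[ok, imap[gi][0]], F[ok, imap[gi][1]]]
            obs = [y[0, 0], y[0, 1], y[1, 0], y[1, 1]]
            acc = np.zeros(ok.sum())
            for mu, ob in zip(mus, obs):
                acc += nb_log_pmf(ob, mu, VF(mu))
            lp[ok] = acc
            logev.append(logsumexp(lp) - np.log(n_mc)
                         + np.log(pri.k_prior_mass[gi]))
        post = np.array(logev)
        post = np.exp(post - post.max())
        post /= post.sum()

        cfg = MHConfig(n_iter=100_000, burn_in=10_000, n_chains=1, seed=17)
        ch = run_mh(d, pri, VF, cfg, grid=grid)
        deltas = ch.post_burn_in(ch.deltas[:, 1])
        emp = np.array([np.mean(np.isclose(deltas, dd)) for dd in grid.deltas])
        assert 0.5 * np.abs(emp - post).sum() < 0.05


class TestPSRF:
    def test_identical_chains_at_lower_limit(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal(500)
        assert psrf([t, t.copy()]) <= 1.0 + 1e-9

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(500)
        b = 10.0 + rng.standard_normal(500)
        assert psrf([a, b]) > 1.1

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        chains = [rng.standard_normal(400) * (1 + 0.1 * i) + 0.2 * i
                  for i in range(4)]
        got = psrf(chains)
        # independently coded Gelman-Rubin
        n = 400
        m = 4
        means = [float(np.mean(c)) for c in chains]
        W = sum(float(np.var(c, ddof=1)) for c in chains) / m
        B_over_n = float(np.var(means, ddof=1))
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            psrf([np.zeros(10)])


def test_run_chains_spawns_independent_seeds():
    y = np.array([[50.0, 80.0, 200.0]])
    d = GeneData(counts=y, size_factors=np.ones((1, 3)), times=[0, 12, 24],
                 replicate_labels=["r1"])
    pri = default_priors(y)
    cfg = MHConfig(n_iter=500, burn_in=100, n_chains=3, seed=21)
    chains = run_chains(d, pri, VF, cfg)
    assert len(chains) == 3
    assert not np.array_equal(chains[0].f, chains[1].f)
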