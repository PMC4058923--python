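import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dynb.model_core import (
    KernelHyperparams,
    TimescaleGrid,
    default_priors,
    delay_prior,
    gp_covariance,
    joint_log_likelihood,
    loglik_from_means,
    nb_log_pmf,
    nb_params_from_moments,
    scaled_times,
    se_kernel,
    timescale_grid,
)
from dynb.normalization import VarianceFunction


class TestSEKernel:
    def test_zero_distance_gives_signal_variance(self):
        th = KernelHyperparams(3.7, 0.8)
        assert se_kernel(24.0, 24.0, th) == pytest.approx(3.7)

    def test_unit_distance_closed_form(self):
        th = KernelHyperparams(1.0, 1.0)
        # one kernel time unit apart
        assert se_kernel(0.0, 1.0, th, time_scale_h=1.0) == pytest.approx(
            np.exp(-0.5)
        )

    @given(
        a=st.floats(-100, 100), b=st.floats(-100, 100),
        t1=st.floats(0.1, 1e4), t2=st.floats(0.05, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, a, b, t1, t2):
        th = KernelHyperparams(t1, t2)
        assert se_kernel(a, b, th) == se_kernel(b, a, th)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            KernelHyperparams(-1.0, 0.5)


class TestGPCovariance:
    def test_single_time(self):
        K = gp_covariance([5.0], KernelHyperparams(2.0, 0.75))
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(2.0 * (1 + 1e-6))

    def test_design_grid_positive_definite(self):
        K = gp_covariance([0.0, 12.0, 24.0, 48.0, 72.0],
                          KernelHyperparams(1.0, 0.75))
        assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_large_theta2_diagonal_limit(self):
        K = gp_covariance([0.0, 12.0, 24.0], KernelHyperparams(1.0, 1e4),
                          time_scale_h=1.0)
        off = K - np.diag(np.diag(K))
        assert np.max(np.abs(off)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_psd_over_prior_support(self, seed):
        rng = np.random.default_rng(seed)
        theta = KernelHyperparams(float(rng.uniform(0.1, 1e6)),
                                  float(rng.uniform(0.5, 1.0)))
        times = np.sort(rng.uniform(0, 104, size=rng.integers(2, 21)))
        K = gp_covariance(times, theta)
        np.linalg.cholesky(K)  # raises if not PD


class TestNegativeBinomial:
    @pytest.mark.parametrize("mu,sigma2,r,p", [(2.0, 4.0, 2.0, 0.5),
                                               (10.0, 20.0, 10.0, 0.5)])
    def test_moment_solution(self, mu, sigma2, r, p):
        assert nb_params_from_moments(mu, sigma2) == pytest.approx((r, p))

    def test_enumerated_pmf_has_requested_moments(self):
        mu, sigma2 = 7.0, 18.0
        y = np.arange(0, 100_000)
        pmf = np.exp(nb_log_pmf(y, mu, sigma2))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert (pmf * y).sum() == pytest.approx(mu, rel=1e-8)
        assert (pmf * (y - mu) ** 2).sum() == pytest.approx(sigma2, rel=1e-6)

    def test_normalizes(self):
        y = np.arange(0, 10_000)
        assert np.exp(nb_log_pmf(y, 5.0, 10.0)).sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("y,mu,sigma2", [(3, 2.0, 4.0), (0, 5.0, 9.0),
                                             (250, 100.0, 900.0)])
    def test_matches_scipy_nbinom(self, y, mu, sigma2):
        r, p = nb_params_from_moments(mu, sigma2)
        # scipy's success probability is the complement of ours
        expected = stats.nbinom.logpmf(y, r, 1.0 - p)
        assert nb_log_pmf(y, mu, sigma2) == pytest.approx(expected, abs=1e-12)

    def test_mode_near_mean(self):
        y = np.arange(0, 400)
        lp = nb_log_pmf(y, 100.0, 150.0)
        assert abs(int(np.argmax(lp)) - 100) <= 2

    def test_poisson_limit(self):
        # agreement in the distribution bulk (y within +-4 sd of mu)
        for mu in (1.0, 5.0, 25.0, 100.0):
            lo = max(int(mu - 4 * np.sqrt(mu)), 0)
            hi = int(mu + 4 * np.sqrt(mu)) + 1
            y = np.arange(lo, hi)
            ours = nb_log_pmf(y, mu, mu * (1 + 1e-6))
            poiss = stats.poisson.logpmf(y, mu)
            assert np.max(np.abs(ours - poiss)) < 1e-3

    def test_underdispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_params_from_moments(5.0, 5.0)


class TestTimescale:
    def test_identity(self):
        t = np.array([0.0, 12.0, 72.0])
        np.testing.assert_array_equal(scaled_times(t, 1.0), t)

    def test_printed_extremes(self):
        assert scaled_times(np.array([72.0]), 5.0 / 9.0)[0] == pytest.approx(40.0)
        assert scaled_times(np.array([72.0]), 13.0 / 9.0)[0] == pytest.approx(104.0)

    def test_default_grid(self):
        g = timescale_grid(72.0, 32.0, 4.0)
        assert g.n == 17
        assert g.ks.min() == pytest.approx(5.0 / 9.0)
        assert g.ks.max() == pytest.approx(13.0 / 9.0)
        assert g.ks[g.identity_index] == pytest.approx(1.0)
        assert g.deltas[g.identity_index] == 0.0

    def test_delta_k_correspondence(self):
        g = timescale_grid(72.0, 32.0, 4.0)
        for d, k in zip(g.deltas, g.ks):
            assert 72.0 * (k - 1.0) == pytest.approx(d)

    def test_divide_convention_reports_inverse_factor(self):
        g = timescale_grid(72.0, 32.0, 4.0, convention="divide")
        assert g.ks.max() == pytest.approx(9.0 / 5.0)
        t = scaled_times(np.array([72.0]), g.ks[0], convention="divide")
        assert t[0] == pytest.approx(72.0 + g.deltas[0])

    def test_indivisible_step_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            timescale_grid(72.0, 32.0, 5.0)

    def test_delay_prior_symmetric_and_normalized(self):
        g = timescale_grid(72.0, 32.0, 4.0)
        mass = delay_prior(g)
        assert mass.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(mass, mass[::-1])


class TestJointLogLikelihood:
    def test_single_observation_reduces_to_nb(self, modest_variance):
        y = np.array([[7.0]])
        f = np.array([10.0])
        ll = joint_log_likelihood(y, f, [0.0], [1.0], np.array([[1.0]]),
                                  modest_variance, eval_times=[0.0])
        expected = nb_log_pmf(7.0, 10.0, modest_variance(10.0))
        assert ll == pytest.approx(float(expected))

    def test_tied_replicates_factorize(self, modest_variance):
        times = np.array([0.0, 12.0, 24.0])
        f = np.array([5.0, 50.0, 500.0])
        y1 = np.array([[4.0, 60.0, 430.0]])
        y3 = np.tile(y1, (3, 1))
        ll1 = joint_log_likelihood(y1, f, times, [1.0], np.ones((1, 3)),
                                   modest_variance, eval_times=times)
        ll3 = joint_log_likelihood(y3, f, times, [1.0] * 3, np.ones((3, 3)),
                                   modest_variance, eval_times=times)
        assert ll3 == pytest.approx(3 * ll1)

    def test_matches_naive_double_loop(self, rng, modest_variance):
        times = np.array([0.0, 12.0, 24.0, 48.0, 72.0])
        grid = timescale_grid(72.0)
        ks = np.array([grid.ks[4], 1.0, grid.ks[12]])
        eval_times = np.unique(np.round(np.concatenate(
            [scaled_times(times, k) for k in ks]), 9))
        f = rng.uniform(10.0, 1000.0, size=eval_times.size)
        sf = rng.uniform(0.7, 1.4, size=(3, 5))
        y = np.rint(rng.uniform(5, 1200, size=(3, 5)))
        ll = joint_log_likelihood(y, f, times, ks, sf, modest_variance,
                                  eval_times=eval_times)
        ref = 0.0
        for j in range(3):
            for i in range(5):
                t_eff = ks[j] * times[i]
                fi = f[np.argmin(np.abs(eval_times - t_eff))]
                mu = sf[j, i] * fi
                ref += float(nb_log_pmf(y[j, i], mu, modest_variance(mu)))
        assert ll == pytest.approx(ref, abs=1e-12)

    def test_nonpositive_mean_gives_minus_inf(self, modest_variance):
        y = np.array([[3.0, 4.0]])
        f = np.array([10.0, -1.0])
        ll = joint_log_likelihood(y, f, [0.0, 12.0], [1.0], np.ones((1, 2)),
                                  modest_variance, eval_times=[0.0, 12.0])
        assert ll == -np.inf

    def test_replicate_permutation_invariance(self, rng, modest_variance):
        times = np.array([0.0, 12.0, 24.0])
        f = rng.uniform(20, 200, size=3)
        y = np.rint(rng.uniform(10, 300, size=(3, 3)))
        sf = rng.uniform(0.8, 1.2, size=(3, 3))
        ll = joint_log_likelihood(y, f, times, [1.0] * 3, sf, modest_variance,
                                  eval_times=times)
        perm = [2, 0, 1]
        ll_p = joint_log_likelihood(y[perm], f, times, [1.0] * 3, sf[perm],
                                    modest_variance, eval_times=times)
        assert ll == pytest.approx(ll_p, abs=1e-12)


class TestDefaultPriors:
    def test_printed_prior_rules(self):
        y = np.array([0, 20, 45, 80, 100])
        pri = default_priors(y)
        assert pri.gp.m == pytest.approx(50.0)
        assert pri.gp.sigma1 == pytest.approx(500.0 * 50.0)
        assert pri.gp.sigma2 == 0.75
        assert pri.theta2_bounds == (0.5, 1.0)
        assert pri.theta1 == pytest.approx(10.0 * np.std(y, ddof=1))

    def test_constant_counts_floor(self):
        pri = default_priors(np.full(15, 42.0))
        assert pri.theta1 == pytest.approx(10.0)

    def test_symmetric_k_prior_by_construction(self):
        g = timescale_grid(72.0)
        pri = default_priors(np.arange(10.0), grid=g)
        np.testing.assert_allclose(pri.k_prior_mass, pri.k_prior_mass[::-1])
        assert pri.k_prior_mass.sum() == pytest.approx(1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            default_priors(np.array([]))
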