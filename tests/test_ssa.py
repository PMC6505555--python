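import numpy as np
import pytest
from scipy.stats import chisquare

from mominf import (
    FeedbackLoopParams,
    HeterogeneousParams,
    TimeGrid,
    add_measurement_noise,
    burst_pmf,
    burst_raw_moments,
    simulate_cell,
    simulate_population,
)

TINY = 1e-12


class TestSingleCell:
    def test_no_production_means_zero_counts(self, grid):
        p = FeedbackLoopParams(TINY, 3, 1, 0.001, 0.1)
        counts = simulate_cell(p, grid, rng_seed=1)
        assert np.all(counts == 0)

    def test_pure_production_is_nondecreasing(self, grid):
        p = FeedbackLoopParams(5, 3, TINY, TINY, 0.1)
        counts = simulate_cell(p, grid, rng_seed=2)
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] > 0

    def test_seed_determinism(self, grid, fig1_params):
        a = simulate_cell(fig1_params, grid, rng_seed=7)
        b = simulate_cell(fig1_params, grid, rng_seed=7)
        c = simulate_cell(fig1_params, grid, rng_seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestPopulation:
    def test_counts_shape_and_small_n(self, grid, fig1_params):
        sample, moments = simulate_population(fig1_params, 2, grid, 2, 0)
        assert sample.counts.shape == (2, 30)
        assert moments.values.shape == (2, 30)

    def test_stationary_moments_match_linear_theory(self):
        # sigma_b = 0: bursty birth-death with mean r*b/d and
        # variance r*(E[m] + E[m^2])/(2d) at stationarity
        r, b, d = 10.0, 3.0, 1.0
        p = FeedbackLoopParams(r, b, d, TINY, 0.1)
        grid = TimeGrid(np.array([15.0, 20.0, 25.0, 30.0]))
        n = 4000
        _, mom = simulate_population(p, n, grid, 4, rng_seed=3)
        e1, e2 = burst_raw_moments(b, 2)
        mean_th = r * b / d
        var_th = r * (e1 + e2) / (2 * d)
        se_mean = np.sqrt(var_th / n)
        mu4 = mom.values[3].mean()
        se_var = np.sqrt((mu4 - var_th**2) / n)
        assert np.all(np.abs(mom.values[0] - mean_th) < 4 * se_mean)
        assert np.all(np.abs(mom.values[1] - var_th) < 4 * se_var)

    def test_two_master_seeds_agree_within_error(self, grid, fig1_params):
        n = 3000
        _, m1 = simulate_population(fig1_params, n, grid, 4, rng_seed=10)
        _, m2 = simulate_population(fig1_params, n, grid, 4, rng_seed=20)
        se = np.sqrt(m1.values[1] / n + m2.values[1] / n)
        assert np.all(np.abs(m1.values[0] - m2.values[0]) < 4 * se)

    def test_heterogeneous_sd_zero_equals_homogeneous(self, grid):
        hp = HeterogeneousParams(13, 0.0, 3, 1, 0.001, 0.1)
        p = FeedbackLoopParams(13, 3, 1, 0.001, 0.1)
        s_het, _ = simulate_population(hp, 50, grid, 2, rng_seed=5)
        s_hom, _ = simulate_population(p, 50, grid, 2, rng_seed=5)
        assert np.array_equal(s_het.counts, s_hom.counts)

    def test_heterogeneous_spread_increases_variance(self, grid):
        hom = HeterogeneousParams(13, 0.0, 5, 1, 0.001, 0.1, rho_u_scale="log")
        het = HeterogeneousParams(13, 0.3, 5, 1, 0.001, 0.1, rho_u_scale="log")
        _, m0 = simulate_population(hom, 4000, grid, 2, rng_seed=6)
        _, m1 = simulate_population(het, 4000, grid, 2, rng_seed=6)
        # log-scale sd 0.3 adds (0.3 * mean)^2 extrinsic variance on top of
        # the intrinsic ~1090: expect a ~15-20% increase
        assert m1.values[1, -5:].mean() > 1.1 * m0.values[1, -5:].mean()


class TestBurstStatistics:
    @pytest.mark.parametrize("b", [1.0, 3.0, 10.0])
    def test_harvested_bursts_follow_geometric_law(self, b):
        # negligible decay/binding and a slow firing rate: positive count
        # increments between consecutive snapshots are single bursts with
        # probability ~ rho_u, so their law is psi conditioned on m >= 1
        rho = 0.02  # rare firings: double bursts per interval are ~1%
        p = FeedbackLoopParams(rho, b, TINY, TINY, 0.1)
        grid = TimeGrid(np.arange(1.0, 31.0))
        sample, _ = simulate_population(p, 6000, grid, 2, rng_seed=int(b))
        inc = np.diff(sample.counts, axis=1).ravel()
        inc = inc[inc > 0]
        assert inc.size > 1000
        k_max = int(np.quantile(inc, 0.99))
        obs = np.bincount(np.minimum(inc, k_max + 1))[1:]
        m = np.arange(1, k_max + 2)
        probs = burst_pmf(b, m)
        probs[-1] = b / (1 + b) - probs[:-1].sum() + probs[-1]  # tail bin
        probs /= probs.sum()
        stat, pval = chisquare(obs, probs * obs.sum())
        assert pval > 0.01


class TestMeasurementNoise:
    def test_zero_scale_is_identity(self, grid, fig1_params):
        sample, _ = simulate_population(fig1_params, 50, grid, 2, 0)
        noisy = add_measurement_noise(sample, 0.0, rng_seed=1)
        assert np.array_equal(noisy.counts, sample.counts)

    def test_negative_scale_rejected(self, grid, fig1_params):
        sample, _ = simulate_population(fig1_params, 10, grid, 2, 0)
        with pytest.raises(ValueError):
            add_measurement_noise(sample, -0.1)

    def test_lognormal_noise_law(self, grid, fig1_params):
        sample, _ = simulate_population(fig1_params, 400, grid, 2, 0)
        scale = 0.05
        noisy = add_measurement_noise(sample, scale, rng_seed=2)
        mask = sample.counts > 0
        logratio = np.log(noisy.counts[mask] / sample.counts[mask])
        # unit-median multiplicative noise: log-ratios are N(0, scale^2)
        assert abs(logratio.mean()) < 4 * scale / np.sqrt(mask.sum())
        assert logratio.std() == pytest.approx(scale, rel=0.05)
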