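import numpy as np
import pytest
from sklearn.base import clone

from mominf import (
    FeedbackLoopParams,
    MomentLikelihoodSpec,
    MomentMCMC,
    MomentMLE,
    MomentSeries,
    TimeGrid,
    default_bounds,
    likelihood_weights,
    neg_log_likelihood,
    predict_moments,
    sampling_variances,
    simulate_population,
)

FIG1 = np.array([13.0, 3.0, 1.0, 0.001, 0.1])


def _skewed_sample_moments(n=10_000, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 10.0, size=n)
    from mominf import sample_central_moments

    values = sample_central_moments(x, 6)[:, None]
    return x, MomentSeries(np.array([1.0]), values, n_cells=n)


class TestSamplingVariances:
    def test_degenerate_data_rejected(self):
        ms = MomentSeries(np.array([1.0]), np.array([[5.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(ValueError):
            sampling_variances(ms, 100, 2)

    def test_finite_n_correction_vanishes_at_infinity(self):
        _, ms = _skewed_sample_moments()
        v_inf = sampling_variances(ms, np.inf, 2)
        v_n = sampling_variances(ms, 10_000, 2)
        mu = ms.values
        # sigma_2^2 * N -> mu4 - mu2^2 as N -> infinity
        assert v_n[1, 0] * 10_000 == pytest.approx(
            v_inf[1, 0], rel=3.0 / 10_000 * 5
        )
        assert v_inf[0, 0] == pytest.approx(mu[1, 0])

    def test_against_bootstrap_oracle(self):
        x, ms = _skewed_sample_moments(n=2000, seed=3)
        v = sampling_variances(ms, 2000, 2)
        rng = np.random.default_rng(99)
        means, variances = [], []
        for _ in range(500):
            xb = rng.choice(x, size=x.size, replace=True)
            means.append(xb.mean())
            variances.append(xb.var())
        boot_v1 = np.var(means)
        boot_v2 = np.var(variances)
        # bootstrap MC error ~ sqrt(2/B) relative
        assert v[0, 0] == pytest.approx(boot_v1, rel=0.3)
        assert v[1, 0] == pytest.approx(boot_v2, rel=0.3)

    def test_requires_enough_orders(self):
        ms = MomentSeries(np.array([1.0]), np.array([[5.0], [2.0]]))
        with pytest.raises(ValueError):
            sampling_variances(ms, 100, 2)

    def test_weight_conventions(self):
        _, ms = _skewed_sample_moments()
        w_s = likelihood_weights(ms, 10_000, 2, "sampling")
        w_m = likelihood_weights(ms, 10_000, 2, "variance-matched")
        mu2 = ms.values[1, 0]
        assert w_s[0, 0] == pytest.approx(mu2 / 10_000)
        assert w_m[0, 0] == pytest.approx(mu2**2 / 10_000)
        assert w_s[1, 0] == w_m[1, 0]
        with pytest.raises(ValueError):
            likelihood_weights(ms, 10_000, 2, "bogus")


class TestNegLogLikelihood:
    def test_zero_at_generating_parameters(self, grid):
        pred = predict_moments("cdm", FeedbackLoopParams(*FIG1), grid, k_max=2)
        spec = MomentLikelihoodSpec(
            pred, np.inf, "cdm", k_max=2,
            weights=np.ones((2, grid.L)),
        )
        assert neg_log_likelihood(FIG1, spec) == pytest.approx(0.0, abs=1e-12)

    def test_weight_rescaling_rescales_objective(self, grid):
        pred = predict_moments("cdm", FeedbackLoopParams(*FIG1), grid, k_max=2)
        w = np.ones((2, grid.L))
        spec1 = MomentLikelihoodSpec(pred, np.inf, "lna", 2, weights=w)
        spec2 = MomentLikelihoodSpec(pred, np.inf, "lna", 2, weights=3.0 * w)
        v1 = neg_log_likelihood(FIG1, spec1)
        v2 = neg_log_likelihood(FIG1, spec2)
        assert v1 > 0
        assert v2 == pytest.approx(v1 / 3.0)

    def test_ridge_flat_with_mean_only_broken_with_variance(
        self, grid, fsp_fig1
    ):
        # the mean depends on rho_u and b only through their product, so a
        # mean-only likelihood cannot identify them individually; adding
        # the variance (burst-size-dependent) breaks the degeneracy
        spec1 = MomentLikelihoodSpec(fsp_fig1, np.inf, "lna", k_max=1)
        spec2 = MomentLikelihoodSpec(fsp_fig1, np.inf, "lna", k_max=2)
        base1 = neg_log_likelihood(FIG1, spec1)
        vals1, vals2 = [], []
        for alpha in (0.5, 0.8, 1.25, 2.0):
            theta = FIG1.copy()
            theta[0] *= alpha
            theta[1] /= alpha
            vals1.append(neg_log_likelihood(theta, spec1))
            vals2.append(neg_log_likelihood(theta, spec2))
        ridge_spread = max(vals1) - min(vals1)
        assert ridge_spread < 1e-4 * max(base1, 1e-30) + 1e-10
        assert min(vals2) > 100 * (ridge_spread + 1e-12)


class TestMomentMLE:
    def test_self_consistency_recovery(self, grid):
        # closure-generated data refit with the same closure recovers the
        # generating parameters essentially exactly
        pred = predict_moments("cdm", FeedbackLoopParams(*FIG1), grid, k_max=2)
        w = np.vstack([pred.order(2) ** 2, pred.order(2) ** 2])
        spec = MomentLikelihoodSpec(pred, np.inf, "cdm", 2, weights=w)
        est = MomentMLE(closure="cdm", bounds_center=FIG1, random_state=0)
        est._fit_spec(spec)
        np.testing.assert_allclose(est.theta_, FIG1, rtol=1e-3)

    def test_seeded_fit_is_reproducible(self, grid, fsp_fig1):
        fits = [
            MomentMLE(closure="lma", bounds_center=FIG1, random_state=5)
            .fit_moments(fsp_fig1, np.inf).theta_
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0], fits[1])

    def test_seed_insensitivity_at_benchmark_conditions(self, grid, fsp_fig1):
        thetas = [
            MomentMLE(closure="lma", bounds_center=FIG1, random_state=s)
            .fit_moments(fsp_fig1, np.inf).theta_
            for s in (1, 2)
        ]
        np.testing.assert_allclose(thetas[0], thetas[1], rtol=1e-3)

    def test_sklearn_protocol(self):
        est = MomentMLE(closure="lma", popsize=7)
        params = est.get_params()
        assert params["closure"] == "lma" and params["popsize"] == 7
        est2 = clone(est).set_params(closure="cdm")
        assert est2.get_params()["closure"] == "cdm"

    def test_fit_from_counts(self, grid):
        p = FeedbackLoopParams(*FIG1)
        sample, _ = simulate_population(p, 2000, grid, 2, rng_seed=4)
        est = MomentMLE(
            closure="lma", time_grid=grid, bounds_center=FIG1,
            random_state=0, maxiter=80,
        )
        est.fit(sample.counts)
        # at N=2000 the estimate is noisy but must sit well inside the box
        assert np.all(est.theta_ > FIG1 / 10)
        assert np.all(est.theta_ < FIG1 * 10)
        assert est.result_.n_cells == 2000

    def test_default_bounds_shape(self):
        b = default_bounds(FIG1)
        assert b.shape == (5, 2)
        np.testing.assert_allclose(b[:, 1] / b[:, 0], 100.0)

    def test_missing_bounds_rejected(self, fsp_fig1):
        with pytest.raises(ValueError):
            MomentMLE(closure="lma").fit_moments(fsp_fig1, np.inf)


class TestMomentMCMC:
    def test_prior_recovery_under_flat_likelihood(self, grid, fsp_fig1):
        # enormous sampling variances flatten the likelihood: the chain
        # must then reproduce the uniform log-space prior box
        w = np.full((2, grid.L), 1e12)
        spec = MomentLikelihoodSpec(fsp_fig1, np.inf, "lna", 2, weights=w)
        est = MomentMCMC(
            closure="lna", bounds_center=FIG1, n_chains=2, n_iter=30_000,
            random_state=1,
        )
        est._fit_spec(spec)
        log_samples = np.log(est.samples_)
        lo, hi = np.log(FIG1 / 10), np.log(FIG1 * 10)
        centre = 0.5 * (lo + hi)
        width = hi - lo
        # uniform moments: mean at centre, sd = width / sqrt(12)
        assert np.all(np.abs(log_samples.mean(axis=0) - centre) < 0.15 * width)
        sd = log_samples.std(axis=0)
        assert np.all(sd > 0.6 * width / np.sqrt(12))
        assert np.all(sd < 1.4 * width / np.sqrt(12))

    def test_chain_reproducibility(self, grid, fsp_fig1):
        kw = dict(
            closure="lma", bounds_center=FIG1, n_chains=2, n_iter=4000,
            random_state=3,
        )
        a = MomentMCMC(**kw).fit_moments(fsp_fig1, np.inf)
        b = MomentMCMC(**kw).fit_moments(fsp_fig1, np.inf)
        np.testing.assert_array_equal(a.samples_, b.samples_)

    def test_rhat_reported_per_parameter(self, grid, fsp_fig1):
        est = MomentMCMC(
            closure="lma", bounds_center=FIG1, n_chains=4, n_iter=10_000,
            random_state=2,
        ).fit_moments(fsp_fig1, np.inf)
        assert est.rhat_.shape == (5,)
        assert np.all(est.rhat_ < 1.2)
        assert est.result_.acceptance_rate is not None
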