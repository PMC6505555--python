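import numpy as np
import pytest

from mominf import (
    CLOSURES,
    ClosurePredictor,
    FeedbackLoopParams,
    HeterogeneousParams,
    TimeGrid,
    fsp_moments,
    fsp_solve,
    predict_moments,
    predict_moments_heterogeneous,
)

TINY = 1e-12


@pytest.fixture(scope="module")
def fsp_linear(grid):
    """Master-equation moments in the decoupled (sigma_b = 0) limit."""
    p = FeedbackLoopParams(13, 3, 1, TINY, 0.1)
    return fsp_moments(fsp_solve(p, grid, n_max=600), 3)


class TestExactnessInLinearLimit:
    @pytest.mark.parametrize("closure", CLOSURES)
    def test_mean_and_variance_exact_at_zero_binding(
        self, closure, grid, fsp_linear
    ):
        p = FeedbackLoopParams(13, 3, 1, TINY, 0.1)
        pred = predict_moments(closure, p, grid, k_max=2)
        for k in (1, 2):
            rel = np.abs(pred.order(k) - fsp_linear.order(k)) / fsp_linear.order(k)
            assert rel.max() < 1e-4, f"{closure} order {k}"

    @pytest.mark.parametrize("closure", ["3ma", "dm", "cdm", "cg", "lma"])
    def test_third_moment_exact_at_zero_binding(self, closure, grid, fsp_linear):
        p = FeedbackLoopParams(13, 3, 1, TINY, 0.1)
        pred = predict_moments(closure, p, grid, k_max=3)
        scale = np.abs(fsp_linear.order(3)).max()
        rel = np.abs(pred.order(3) - fsp_linear.order(3)) / scale
        assert rel.max() < 1e-4


class TestClosureStructure:
    def test_lna_third_central_moment_identically_zero(self, grid, fig1_params):
        pred = predict_moments("lna", fig1_params, grid, k_max=3)
        assert np.all(pred.order(3) == 0.0)

    def test_short_time_agreement_with_master_equation(self, fig1_params):
        short = TimeGrid(np.array([0.02, 0.05, 0.1]))
        exact = fsp_moments(fsp_solve(fig1_params, short, n_max=390), 2)
        for closure in CLOSURES:
            pred = predict_moments(closure, fig1_params, short, k_max=2)
            for k in (1, 2):
                rel = np.abs(pred.order(k) - exact.order(k)) / exact.order(k)
                assert rel.max() < 0.01, closure

    def test_conditional_closures_track_master_equation_closely(
        self, grid, fig1_params, fsp_fig1
    ):
        # at the reference parameter set CDM and CG stay within ~0.1%
        for closure in ("cdm", "cg"):
            pred = predict_moments(closure, fig1_params, grid, k_max=2)
            for k in (1, 2):
                rel = np.abs(pred.order(k) - fsp_fig1.order(k)) / fsp_fig1.order(k)
                assert rel.max() < 1e-3, closure

    def test_unsupported_options_rejected(self, grid, fig1_params):
        with pytest.raises(ValueError):
            ClosurePredictor("nope")
        with pytest.raises(ValueError):
            ClosurePredictor("lna", k_max=4)


@pytest.fixture(scope="module")
def errors_by_sigma_b(grid):
    from mominf.closures import ClosureDivergenceError

    out = {}
    for sb in (1e-4, 1e-3, 1e-2):
        p = FeedbackLoopParams(13, 3, 1, sb, 0.1)
        exact = fsp_moments(fsp_solve(p, grid), 2)
        row = {}
        for closure in CLOSURES:
            try:
                pred = predict_moments(closure, p, grid, k_max=2)
            except ClosureDivergenceError:
                # finite-time blow-up: infinite systematic error
                row[closure] = np.inf
                continue
            row[closure] = sum(
                (np.abs(pred.order(k) - exact.order(k)) / exact.order(k)).sum()
                for k in (1, 2)
            )
        out[sb] = row
    return out


class TestErrorOrdering:
    @pytest.mark.parametrize("closure", ["lna", "3ma"])
    def test_error_grows_with_binding_rate(self, errors_by_sigma_b, closure):
        errs = [errors_by_sigma_b[sb][closure] for sb in (1e-4, 1e-3, 1e-2)]
        assert errs[0] <= errs[1] <= errs[2]

    def test_conditional_and_mapping_closures_beat_expansion_closures(
        self, errors_by_sigma_b
    ):
        # at the strongest feedback tested, CDM/CG/LMA moment errors sit an
        # order of magnitude below 3MA's
        row = errors_by_sigma_b[1e-2]
        for good in ("cdm", "cg", "lma"):
            assert row[good] * 10 < row["3ma"]


class TestHeterogeneous:
    def test_sd_zero_reduces_to_homogeneous(self, grid):
        hp = HeterogeneousParams(13, 0.0, 5, 1, 0.001, 0.1)
        hom = FeedbackLoopParams(13, 5, 1, 0.001, 0.1)
        a = predict_moments_heterogeneous("cdm", hp, grid, 2)
        b = predict_moments("cdm", hom, grid, 2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mixture_mean_is_quadrature_average(self, grid):
        hp = HeterogeneousParams(13, 0.3, 5, 1, 0.001, 0.1, rho_u_scale="log")
        mix = predict_moments_heterogeneous("cdm", hp, grid, 2, n_quad=12)
        x, w = np.polynomial.hermite.hermgauss(12)
        mu, sig = hp.lognormal_log_params()
        acc = np.zeros(grid.L)
        for xi, wi in zip(x, w):
            rho = float(np.exp(mu + np.sqrt(2) * sig * xi))
            cond = predict_moments(
                "cdm", FeedbackLoopParams(rho, 5, 1, 0.001, 0.1), grid, 2
            )
            acc += wi / np.sqrt(np.pi) * cond.order(1)
        np.testing.assert_allclose(mix.order(1), acc, rtol=1e-10)

    def test_quadrature_convergence(self, grid):
        hp = HeterogeneousParams(13, 0.3, 5, 1, 0.001, 0.1, rho_u_scale="log")
        a = predict_moments_heterogeneous("cdm", hp, grid, 2, n_quad=20)
        b = predict_moments_heterogeneous("cdm", hp, grid, 2, n_quad=40)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)

    def test_mixture_against_stratified_master_equation(self, grid):
        # oracle: the same lognormal mixture assembled from per-node FSP
        # solves; the closure mixture must agree within the homogeneous
        # closure error (~0.1% for CDM)
        hp = HeterogeneousParams(13, 0.3, 5, 1, 0.001, 0.1, rho_u_scale="log")
        n_quad = 8
        mix = predict_moments_heterogeneous("cdm", hp, grid, 2, n_quad=n_quad)
        x, w = np.polynomial.hermite.hermgauss(n_quad)
        mu, sig = hp.lognormal_log_params()
        raw = np.zeros((2, grid.L))
        for xi, wi in zip(x, w):
            rho = float(np.exp(mu + np.sqrt(2) * sig * xi))
            m = fsp_moments(
                fsp_solve(FeedbackLoopParams(rho, 5, 1, 0.001, 0.1), grid), 2
            )
            wt = wi / np.sqrt(np.pi)
            raw[0] += wt * m.order(1)
            raw[1] += wt * (m.order(2) + m.order(1) ** 2)
        mean = raw[0]
        var = raw[1] - mean**2
        assert np.max(np.abs(mix.order(1) - mean) / mean) < 2e-3
        assert np.max(np.abs(mix.order(2) - var) / var) < 2e-3
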