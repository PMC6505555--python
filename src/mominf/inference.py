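"""Moment-based likelihoods and the two parameter estimators.

The likelihood of observed central moments given parameters is a product of
independent Gaussians, one per moment order and time point: by the central
limit theorem the sample moments of a large cell population are
approximately Gaussian around the master-equation moments, with sampling
variances expressible through higher sample moments,

    sigma_1^2 = mu_2 / N,
    sigma_2^2 = (mu_4 - (N-3)/(N-1) mu_2^2) / N,
    sigma_3^2 = (mu_6 - mu_3^2) / N.

Maximising the likelihood is equivalent to minimising the weighted squared
mismatch  sum_{k,l} (mu_hat_k(t_l) - mu_tilde_k(t_l, theta))^2 / sigma_k^2,
with the model moments mu_tilde supplied by a moment closure.  For
effectively infinite samples (master-equation "data") the common 1/N factor
cancels from the argmin.

Two weight conventions are supported for the first-moment term.  The default
``"variance-matched"`` uses ``sigma_1^2 = mu_2^2 / N``, which makes the mean
and variance mismatches enter on a common relative scale (both weights are
then of order ``mu_2^2``, so neither moment dominates the objective purely
through its units); ``"sampling"`` uses the exact CLT sampling variance
``mu_2 / N``, which weights the (much more precisely measured) mean far more
strongly.  :func:`sampling_variances` always returns the exact statistical
quantities regardless of the fitting convention.

Two estimators are provided as scikit-learn style classes:

- :class:`MomentMLE` - global minimisation of the mismatch by differential
  evolution over ln(theta) (positivity via the ln-exp transform), followed
  by a local polish.
- :class:`MomentMCMC` - adaptive Metropolis sampling of the posterior under
  a uniform prior on ln(theta); the point estimate is the posterior mode
  (MAP) extracted from a kernel density over the samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import differential_evolution
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from . import _kernels
from .model import FeedbackLoopParams, HeterogeneousParams, Params, TimeGrid
from .moments import MomentSeries

__all__ = [
    "MomentLikelihoodSpec",
    "FitResult",
    "sampling_variances",
    "likelihood_weights",
    "neg_log_likelihood",
    "MomentMLE",
    "MomentMCMC",
    "mle_fit",
    "mcmc_fit",
    "default_bounds",
]


def sampling_variances(
    moments: MomentSeries, n_cells: Union[int, float], k_max: int
) -> np.ndarray:
    """Sampling variances ``sigma_k^2(t_l)`` of the first ``k_max`` moments.

    Requires observed central moments up to order ``2 k_max``.  For
    ``n_cells = inf`` (master-equation data) the overall 1/N factor and the
    finite-N correction ``(N-3)/(N-1)`` are dropped; the resulting weights
    give the same argmin (the factor is common to all terms).
    """
    if k_max not in (1, 2, 3):
        raise ValueError("k_max must be 1, 2 or 3")
    if moments.K < 2 * k_max:
        raise ValueError(
            f"need moments up to order {2 * k_max}, have K={moments.K}"
        )
    N = n_cells
    infinite = np.isinf(N)
    if not infinite:
        N = int(N)
        if N < 4:
            raise ValueError("need at least 4 cells for sampling variances")
    mu = moments.values
    out = np.empty((k_max, moments.L))
    out[0] = mu[1]
    if k_max >= 2:
        c = 1.0 if infinite else (N - 3.0) / (N - 1.0)
        out[1] = mu[3] - c * mu[1] ** 2
    if k_max >= 3:
        out[2] = mu[5] - mu[2] ** 2
    if not infinite:
        out /= N
    if np.any(out <= 0):
        raise ValueError(
            "nonpositive sampling variance: degenerate moment data"
        )
    return out


def likelihood_weights(
    moments: MomentSeries,
    n_cells: Union[int, float],
    k_max: int,
    convention: str = "variance-matched",
) -> np.ndarray:
    """Per-moment weights ``sigma_k^2(t_l)`` used in the fitting objective.

    ``"variance-matched"`` (default) replaces the first-moment weight by
    ``mu_2^2 / N`` so mean and variance mismatches are commensurate;
    ``"sampling"`` uses the exact sampling variances.  Overall 1/N factors
    are dropped for infinite-sample data (argmin-invariant).
    """
    if convention not in ("variance-matched", "sampling"):
        raise ValueError(f"unknown weight convention {convention!r}")
    out = sampling_variances(moments, n_cells, k_max)
    if convention == "variance-matched":
        mu2 = moments.values[1]
        out = out.copy()
        out[0] = mu2**2 if np.isinf(n_cells) else mu2**2 / int(n_cells)
    return out


@dataclass
class MomentLikelihoodSpec:
    """Everything needed to evaluate the moment likelihood at a parameter.

    ``observed`` must contain central moments up to order ``2 k_max`` so the
    sampling variances can be formed; only orders ``1..k_max`` enter the
    mismatch.  ``n_cells = inf`` marks master-equation (infinite-sample)
    data.
    """

    observed: MomentSeries
    n_cells: Union[int, float]
    closure_id: str
    k_max: int = 2
    heterogeneous: bool = False
    n_quad: int = 20
    rho_u_scale: str = "arithmetic"
    weight_convention: str = "variance-matched"
    weights: Optional[np.ndarray] = None  # explicit sigma_k^2, (k_max, L)

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.variances = np.asarray(self.weights, dtype=float)
            if self.variances.shape != (self.k_max, self.observed.L):
                raise ValueError("explicit weights must have shape (k_max, L)")
            if np.any(self.variances <= 0):
                raise ValueError("explicit weights must be positive")
        else:
            self.variances = likelihood_weights(
                self.observed, self.n_cells, self.k_max, self.weight_convention
            )
        self.cid = _kernels.CID[self.closure_id]
        L = self.observed.L
        data = np.zeros((3, L))
        w = np.zeros((3, L))
        data[: self.k_max] = self.observed.values[: self.k_max]
        w[: self.k_max] = 1.0 / self.variances
        self._data = data
        self._weights = w
        self._gh_x, self._gh_w = np.polynomial.hermite.hermgauss(self.n_quad)
        self._scale_flag = 1 if self.rho_u_scale == "log" else 0

    @property
    def n_params(self) -> int:
        return 6 if self.heterogeneous else 5

    def chi2(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        return float(
            _kernels.chi2(
                self.cid, theta, 1 if self.heterogeneous else 0,
                self._scale_flag, self._gh_x, self._gh_w,
                self.observed.times, self._data, self._weights,
            )
        )

    def chi2_batch_log(self, log_thetas: np.ndarray) -> np.ndarray:
        return _kernels.chi2_batch(
            self.cid, np.ascontiguousarray(log_thetas),
            1 if self.heterogeneous else 0, self._scale_flag,
            self._gh_x, self._gh_w,
            self.observed.times, self._data, self._weights,
        )

    def params_from_theta(self, theta: np.ndarray) -> Params:
        if self.heterogeneous:
            return HeterogeneousParams.from_array(theta, self.rho_u_scale)
        return FeedbackLoopParams.from_array(theta)


def neg_log_likelihood(theta: np.ndarray, spec: MomentLikelihoodSpec) -> float:
    """Weighted moment mismatch (twice the negative log-likelihood up to
    constants); flagged closure evaluations return a large finite penalty."""
    return spec.chi2(theta)


def default_bounds(
    center: Union[np.ndarray, Params], decades: float = 1.0
) -> np.ndarray:
    """Positivity box ``[center/10^decades, center*10^decades]`` per parameter."""
    if isinstance(center, (FeedbackLoopParams, HeterogeneousParams)):
        center = center.as_array()
    center = np.asarray(center, dtype=float)
    if np.any(center <= 0):
        raise ValueError("bounds center must be strictly positive")
    f = 10.0 ** decades
    return np.column_stack([center / f, center * f])


@dataclass
class FitResult:
    """Point estimate plus estimator diagnostics and provenance."""

    theta: np.ndarray
    params: Params
    method: str
    objective: float
    closure_id: str
    k_max: int
    n_cells: Union[int, float]
    L: int
    seed: Optional[int]
    n_evaluations: Optional[int] = None
    converged: bool = True
    acceptance_rate: Optional[float] = None
    rhat: Optional[np.ndarray] = None
    marginal_modes: Optional[np.ndarray] = None
    samples: Optional[np.ndarray] = None  # posterior draws (MCMC only)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "method": self.method,
            "theta": self.theta.tolist(),
            "objective": self.objective,
            "closure_id": self.closure_id,
            "k_max": self.k_max,
            "n_cells": None if np.isinf(self.n_cells) else int(self.n_cells),
            "L": self.L,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "converged": bool(self.converged),
            "acceptance_rate": self.acceptance_rate,
            "rhat": None if self.rhat is None else self.rhat.tolist(),
            "marginal_modes": (
                None if self.marginal_modes is None
                else self.marginal_modes.tolist()
            ),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class MomentMLE(BaseEstimator):
    """Maximum-likelihood estimation of feedback-loop parameters.

    Minimises the weighted moment mismatch over ``ln(theta)`` with
    differential evolution (population ``popsize * n_params``), then
    polishes locally.  Deterministic for a fixed ``random_state``.

    Parameters
    ----------
    closure : str
        Moment-closure scheme approximating the likelihood.
    k_max : int
        Highest observed moment order used (2 or 3).
    bounds : (p, 2) array, optional
        Positivity box for theta; defaults to ``default_bounds(bounds_center)``.
    bounds_center : array or params, optional
        Centre of the default box (e.g. the generating parameters of a
        synthetic study, mirroring a wide prior).
    heterogeneous : bool
        Fit the six-parameter non-identical-cell model.

    Attributes
    ----------
    theta_ : (p,) array
        Estimated parameter vector.
    params_ : FeedbackLoopParams or HeterogeneousParams
    objective_ : float
        Final weighted mismatch value.
    result_ : FitResult
    """

    def __init__(
        self,
        closure: str = "cdm",
        k_max: int = 2,
        heterogeneous: bool = False,
        n_quad: int = 20,
        rho_u_scale: str = "arithmetic",
        weight_convention: str = "variance-matched",
        time_grid: Optional[TimeGrid] = None,
        bounds: Optional[np.ndarray] = None,
        bounds_center: Optional[Union[np.ndarray, Params]] = None,
        bounds_decades: float = 1.0,
        popsize: int = 15,
        maxiter: int = 400,
        tol: float = 1e-10,
        mutation=(0.5, 1.0),
        recombination: float = 0.9,
        init: str = "sobol",
        random_state: int = 0,
    ):
        self.closure = closure
        self.k_max = k_max
        self.heterogeneous = heterogeneous
        self.n_quad = n_quad
        self.rho_u_scale = rho_u_scale
        self.weight_convention = weight_convention
        self.time_grid = time_grid
        self.bounds = bounds
        self.bounds_center = bounds_center
        self.bounds_decades = bounds_decades
        self.popsize = popsize
        self.maxiter = maxiter
        self.tol = tol
        self.mutation = mutation
        self.recombination = recombination
        self.init = init
        self.random_state = random_state

    # -- data preparation ---------------------------------------------------

    def _spec_from_counts(self, X: np.ndarray) -> MomentLikelihoodSpec:
        if self.time_grid is None:
            raise ValueError("time_grid is required when fitting raw counts")
        from .ssa import SnapshotSample

        sample = SnapshotSample(np.asarray(X), self.time_grid.times)
        observed = sample.central_moments(2 * self.k_max)
        return MomentLikelihoodSpec(
            observed, sample.n_cells, self.closure, self.k_max,
            self.heterogeneous, self.n_quad, self.rho_u_scale,
            self.weight_convention,
        )

    def _bounds(self) -> np.ndarray:
        if self.bounds is not None:
            return np.asarray(self.bounds, dtype=float)
        if self.bounds_center is None:
            raise ValueError("provide either bounds or bounds_center")
        return default_bounds(self.bounds_center, self.bounds_decades)

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "MomentMLE":
        """Fit from a cells-by-times count matrix ``X``."""
        return self._fit_spec(self._spec_from_counts(X))

    def fit_moments(
        self, observed: MomentSeries, n_cells: Union[int, float]
    ) -> "MomentMLE":
        """Fit from precomputed central moments (orders up to ``2 k_max``).

        Use ``n_cells=np.inf`` for master-equation (infinite-sample) data.
        """
        spec = MomentLikelihoodSpec(
            observed, n_cells, self.closure, self.k_max,
            self.heterogeneous, self.n_quad, self.rho_u_scale,
            self.weight_convention,
        )
        return self._fit_spec(spec)

    def _fit_spec(self, spec: MomentLikelihoodSpec) -> "MomentMLE":
        bounds = self._bounds()
        if bounds.shape != (spec.n_params, 2):
            raise ValueError(
                f"bounds shape {bounds.shape} != ({spec.n_params}, 2)"
            )
        log_bounds = list(np.log(bounds))

        def objective(x):
            # x: (p,) scalar call or (p, S) vectorised population call
            if x.ndim == 1:
                return float(spec.chi2_batch_log(x[None, :])[0])
            return spec.chi2_batch_log(x.T)

        res = differential_evolution(
            objective,
            log_bounds,
            seed=self.random_state,
            popsize=self.popsize,
            maxiter=self.maxiter,
            tol=self.tol,
            mutation=self.mutation,
            recombination=self.recombination,
            init=self.init,
            polish=True,
            vectorized=True,
            updating="deferred",
        )
        theta = np.exp(res.x)
        self.spec_ = spec
        self.theta_ = theta
        self.params_ = spec.params_from_theta(theta)
        self.objective_ = float(res.fun)
        self.n_evaluations_ = int(res.nfev)
        self.result_ = FitResult(
            theta=theta,
            params=self.params_,
            method="mle",
            objective=self.objective_,
            closure_id=spec.closure_id,
            k_max=spec.k_max,
            n_cells=spec.n_cells,
            L=spec.observed.L,
            seed=self.random_state,
            n_evaluations=self.n_evaluations_,
            converged=bool(res.success),
        )
        return self

    def predict(self, time_grid: Optional[TimeGrid] = None) -> MomentSeries:
        """Predicted central moments at the fitted parameters."""
        from .closures import ClosurePredictor

        grid = time_grid or TimeGrid(self.spec_.observed.times)
        pred = ClosurePredictor(
            self.closure, min(self.k_max, 3) if self.k_max >= 2 else 2,
            self.heterogeneous, self.n_quad,
        )
        return pred.predict(self.params_, grid)


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin split-R-hat per parameter; ``chains`` is (C, S, p)."""
    C, S, p = chains.shape
    half = S // 2
    segs = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = segs.shape[0], half
    means = segs.mean(axis=1)  # (m, p)
    variances = segs.var(axis=1, ddof=1)  # (m, p)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return np.sqrt(var_plus / W)


class MomentMCMC(BaseEstimator):
    """Bayesian posterior sampling with an adaptive Metropolis sampler.

    The chain walks in ``ln(theta)`` under a uniform prior on the log-space
    box; the proposal covariance adapts to the running chain covariance
    after a non-adaptive warm start.  Several independent chains are run
    (different seeds) and convergence is summarised by split-R-hat.  The MAP
    estimate is the posterior-sample argmax of a Gaussian kernel density in
    log-space; marginal (per-parameter) modes are also reported.

    Attributes
    ----------
    samples_ : (C * S_keep, p) array of posterior draws (theta scale).
    map_ : (p,) MAP estimate.
    marginal_modes_ : (p,) per-parameter marginal KDE modes.
    rhat_ : (p,) split-R-hat.
    """

    def __init__(
        self,
        closure: str = "cdm",
        k_max: int = 2,
        heterogeneous: bool = False,
        n_quad: int = 20,
        rho_u_scale: str = "arithmetic",
        weight_convention: str = "variance-matched",
        time_grid: Optional[TimeGrid] = None,
        bounds: Optional[np.ndarray] = None,
        bounds_center: Optional[Union[np.ndarray, Params]] = None,
        bounds_decades: float = 1.0,
        n_chains: int = 4,
        n_iter: int = 100_000,
        burn_in: Optional[int] = None,
        rhat_threshold: float = 1.1,
        kde_subsample: int = 4000,
        random_state: int = 0,
    ):
        self.closure = closure
        self.k_max = k_max
        self.heterogeneous = heterogeneous
        self.n_quad = n_quad
        self.rho_u_scale = rho_u_scale
        self.weight_convention = weight_convention
        self.time_grid = time_grid
        self.bounds = bounds
        self.bounds_center = bounds_center
        self.bounds_decades = bounds_decades
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.rhat_threshold = rhat_threshold
        self.kde_subsample = kde_subsample
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "MomentMCMC":
        helper = MomentMLE(
            closure=self.closure, k_max=self.k_max,
            heterogeneous=self.heterogeneous, n_quad=self.n_quad,
            rho_u_scale=self.rho_u_scale,
            weight_convention=self.weight_convention,
            time_grid=self.time_grid,
        )
        return self._fit_spec(helper._spec_from_counts(X))

    def fit_moments(
        self, observed: MomentSeries, n_cells: Union[int, float]
    ) -> "MomentMCMC":
        spec = MomentLikelihoodSpec(
            observed, n_cells, self.closure, self.k_max,
            self.heterogeneous, self.n_quad, self.rho_u_scale,
            self.weight_convention,
        )
        return self._fit_spec(spec)

    def _fit_spec(self, spec: MomentLikelihoodSpec) -> "MomentMCMC":
        bounds = MomentMLE._bounds(self)  # same box logic
        if bounds.shape != (spec.n_params, 2):
            raise ValueError(
                f"bounds shape {bounds.shape} != ({spec.n_params}, 2)"
            )
        log_lo = np.log(bounds[:, 0])
        log_hi = np.log(bounds[:, 1])
        burn = self.burn_in if self.burn_in is not None else self.n_iter // 2
        ss = np.random.SeedSequence(self.random_state)
        chain_seeds = ss.generate_state(self.n_chains)
        init_rng = np.random.default_rng(ss.spawn(1)[0])

        kept = []
        logp_kept = []
        accepts = []
        centre = 0.5 * (log_lo + log_hi)
        for c in range(self.n_chains):
            # modestly dispersed starts around the box centre
            x0 = centre + 0.1 * init_rng.standard_normal(spec.n_params)
            samples, logp, acc = _kernels.am_chain(
                spec.cid, 1 if spec.heterogeneous else 0,
                spec._scale_flag, spec._gh_x, spec._gh_w,
                spec.observed.times, spec._data, spec._weights,
                log_lo, log_hi, x0, int(self.n_iter),
                int(chain_seeds[c] % (2**31 - 1)),
            )
            kept.append(samples[burn:])
            logp_kept.append(logp[burn:])
            accepts.append(acc / self.n_iter)

        chains = np.stack(kept)  # (C, S, p) in log-space
        self.rhat_ = split_rhat(chains)
        flat_log = chains.reshape(-1, spec.n_params)
        flat_logp = np.concatenate(logp_kept)

        # MAP: KDE over a thinned subsample in log-space
        rng = np.random.default_rng(self.random_state)
        idx = (
            np.arange(flat_log.shape[0])
            if flat_log.shape[0] <= self.kde_subsample
            else rng.choice(flat_log.shape[0], self.kde_subsample, replace=False)
        )
        sub = flat_log[idx]
        try:
            kde = gaussian_kde(sub.T)
            dens = kde(sub.T)
            map_log = sub[int(np.argmax(dens))]
        except np.linalg.LinAlgError:
            # near-degenerate posterior: fall back to highest-posterior draw
            map_log = flat_log[int(np.argmax(flat_logp))]
        marg = np.empty(spec.n_params)
        for j in range(spec.n_params):
            kj = gaussian_kde(sub[:, j])
            gridj = np.linspace(sub[:, j].min(), sub[:, j].max(), 512)
            marg[j] = gridj[int(np.argmax(kj(gridj)))]

        self.spec_ = spec
        self.samples_ = np.exp(flat_log)
        self.logp_ = flat_logp
        self.map_ = np.exp(map_log)
        self.marginal_modes_ = np.exp(marg)
        self.acceptance_ = float(np.mean(accepts))
        self.theta_ = self.map_
        self.params_ = spec.params_from_theta(self.map_)
        self.converged_ = bool(np.all(self.rhat_ < self.rhat_threshold))
        self.result_ = FitResult(
            theta=self.map_,
            params=self.params_,
            method="mcmc-map",
            objective=spec.chi2(self.map_),
            closure_id=spec.closure_id,
            k_max=spec.k_max,
            n_cells=spec.n_cells,
            L=spec.observed.L,
            seed=self.random_state,
            converged=self.converged_,
            acceptance_rate=self.acceptance_,
            rhat=self.rhat_,
            marginal_modes=self.marginal_modes_,
            samples=self.samples_,
        )
        return self


def mle_fit(
    spec: MomentLikelihoodSpec,
    bounds: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`MomentMLE` for a prepared spec."""
    est = MomentMLE(
        closure=spec.closure_id, k_max=spec.k_max,
        heterogeneous=spec.heterogeneous, n_quad=spec.n_quad,
        rho_u_scale=spec.rho_u_scale,
        weight_convention=spec.weight_convention, bounds=bounds,
        random_state=seed, **kwargs,
    )
    est._fit_spec(spec)
    return est.result_


def mcmc_fit(
    spec: MomentLikelihoodSpec,
    bounds: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`MomentMCMC` for a prepared spec."""
    est = MomentMCMC(
        closure=spec.closure_id, k_max=spec.k_max,
        heterogeneous=spec.heterogeneous, n_quad=spec.n_quad,
        rho_u_scale=spec.rho_u_scale,
        weight_convention=spec.weight_convention, bounds=bounds,
        random_state=seed, **kwargs,
    )
    est._fit_spec(spec)
    return est.result_
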