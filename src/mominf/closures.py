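"""Moment-closure predictions of protein central moments over time.

Six approximations of the chemical master equation are available, each
producing a closed ODE system for the first three protein moments from the
zero-protein gene-ON initial state:

``lna``
    Linear noise approximation: deterministic rate equations for the gene-ON
    probability and mean protein number plus a Lyapunov equation for the
    Gaussian covariance, with burst-augmented diffusion.  Its third central
    moment is identically zero.
``3ma``
    Three-moment approximation: the exact joint raw-moment equations of the
    (gene, protein) pair up to order three, closed by zero fourth joint
    cumulants.  The gene is treated as an ordinary species (the binary
    identity y^2 = y is not exploited), as in standard moment-closure
    practice.
``dm``
    Derivative matching: same hierarchy, with unclosed fourth-order moments
    replaced by products of lower moments whose exponents make the closure
    exact for jointly lognormal statistics.
``cdm`` / ``cg``
    Conditional closures: gene-state probabilities plus protein moments
    conditional on the gene state; the third conditional moments are closed
    by derivative matching (``cdm``) or by a zero conditional third cumulant
    (``cg``, a conditional Gaussian).
``lma``
    Linear-mapping approximation: the protein-DNA binding reaction is
    replaced by a first-order gene switch whose rate ``sigma_b * E[n | ON]``
    is updated self-consistently during integration; the mapped bursty
    telegraph system has exactly closed moment equations.

For heterogeneous (non-identical) cell populations the burst-firing rate
``rho_u`` is lognormal across cells; population moments are computed by
Gauss-Hermite quadrature over the mixture (law of total expectation applied
to the raw moments of the conditional, fixed-``rho_u`` predictions).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .model import FeedbackLoopParams, HeterogeneousParams, Params, TimeGrid
from .moments import MomentSeries

__all__ = [
    "CLOSURES",
    "ClosureDivergenceError",
    "ClosurePredictor",
    "predict_moments",
    "predict_moments_heterogeneous",
]

CLOSURES = ("lna", "3ma", "dm", "cdm", "cg", "lma")


class ClosureDivergenceError(RuntimeError):
    """The closure ODE system blew up for the requested parameters."""


def _quad_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.hermite.hermgauss(n_quad)


class ClosurePredictor:
    """Generator of predicted central moments for one closure scheme.

    Parameters
    ----------
    closure_id : str
        One of ``lna, 3ma, dm, cdm, cg, lma``.
    k_max : int
        Highest central moment order returned (2 or 3).
    heterogeneous : bool
        Expect :class:`HeterogeneousParams` and average over the lognormal
        ``rho_u`` mixture.
    n_quad : int
        Gauss-Hermite nodes for the mixture average (heterogeneous only).
    """

    def __init__(
        self,
        closure_id: str,
        k_max: int = 2,
        heterogeneous: bool = False,
        n_quad: int = 20,
    ):
        if closure_id not in CLOSURES:
            raise ValueError(f"unknown closure {closure_id!r}; options {CLOSURES}")
        if k_max not in (2, 3):
            raise ValueError("k_max must be 2 or 3")
        self.closure_id = closure_id
        self.cid = _kernels.CID[closure_id]
        self.k_max = k_max
        self.heterogeneous = heterogeneous
        self.n_quad = n_quad
        self._gh_x, self._gh_w = _quad_nodes(n_quad)

    def predict(self, params: Params, time_grid: TimeGrid) -> MomentSeries:
        """Integrate the closure and return central moments ``1..k_max``.

        A prediction with a negative variance anywhere on the grid is
        returned with ``flagged=True`` (the likelihood treats it as an
        infinite penalty); ODE blow-up raises
        :class:`ClosureDivergenceError`.
        """
        times = time_grid.times
        raw = np.empty((3, times.size))
        if self.heterogeneous:
            if not isinstance(params, HeterogeneousParams):
                raise TypeError("heterogeneous predictor needs HeterogeneousParams")
            scale_flag = 1 if params.rho_u_scale == "log" else 0
            ok = _kernels.closure_raw_het(
                self.cid, params.as_array(), scale_flag,
                self._gh_x, self._gh_w, times, raw,
            )
        else:
            if isinstance(params, HeterogeneousParams):
                raise TypeError("homogeneous predictor needs FeedbackLoopParams")
            ok = _kernels.closure_raw(self.cid, params.as_array(), times, raw)
        if not ok:
            raise ClosureDivergenceError(
                f"{self.closure_id} closure diverged for {params}"
            )
        central = np.empty_like(raw)
        _kernels.raw_to_central(raw, central)
        flagged = bool(np.any(central[1] < -1e-6 * (1.0 + np.abs(raw[1]))))
        return MomentSeries(
            times, central[: self.k_max], source="closure",
            n_cells=None, flagged=flagged,
        )


def predict_moments(
    closure_id: str,
    params: FeedbackLoopParams,
    time_grid: TimeGrid,
    k_max: int = 2,
) -> MomentSeries:
    """Closure-predicted central moments for identical cells."""
    return ClosurePredictor(closure_id, k_max).predict(params, time_grid)


def predict_moments_heterogeneous(
    closure_id: str,
    params: HeterogeneousParams,
    time_grid: TimeGrid,
    k_max: int = 2,
    n_quad: int = 20,
) -> MomentSeries:
    """Closure-predicted population moments for lognormal-``rho_u`` cells."""
    return ClosurePredictor(
        closure_id, k_max, heterogeneous=True, n_quad=n_quad
    ).predict(params, time_grid)
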