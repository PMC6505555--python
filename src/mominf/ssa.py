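"""Synthetic single-cell data: exact stochastic simulation of the feedback loop.

Each cell is one realization of the Gillespie direct method for the reaction
scheme in :mod:`mominf.model`, started from zero proteins with the gene ON.
Population snapshot moments are computed across cells per time point;
following the study design, moments at different time points are treated as
independent (the snapshot assumption of flow-cytometry-style data).

Cell-to-cell heterogeneity: for :class:`~mominf.model.HeterogeneousParams`
each cell draws its own burst-firing rate ``rho_u`` from the configured
lognormal before simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import _kernels
from .model import FeedbackLoopParams, HeterogeneousParams, Params, TimeGrid
from .moments import MomentSeries, sample_central_moments

__all__ = [
    "SnapshotSample",
    "simulate_cell",
    "simulate_population",
    "add_measurement_noise",
]


@dataclass
class SnapshotSample:
    """Protein counts ``x_i(t_l)`` for ``N`` cells at ``L`` time points."""

    counts: np.ndarray  # (N, L); integer, or float after measurement noise
    times: np.ndarray
    params: Optional[Params] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.shape[1] != self.times.size:
            raise ValueError("counts and times have incompatible shapes")
        if np.any(self.counts < 0):
            raise ValueError("protein counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def central_moments(self, k_max: int = 2) -> MomentSeries:
        """Sample central moments per time point (1/N normalisation)."""
        values = np.empty((k_max, self.times.size))
        for l in range(self.times.size):
            values[:, l] = sample_central_moments(self.counts[:, l], k_max)
        return MomentSeries(
            self.times, values, source="sample", n_cells=self.n_cells
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        header = ",".join(f"t={t:g}" for t in self.times)
        np.savetxt(path, self.counts, delimiter=",", header=header, fmt="%g")


def _cell_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-cell RNG seeds spawned from one master seed.

    Uses a SeedSequence so changing N extends rather than reshuffles the
    stream assignment.
    """
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n).astype(np.int64)


def simulate_cell(
    params: FeedbackLoopParams, time_grid: TimeGrid, rng_seed: int
) -> np.ndarray:
    """SSA trajectory of a single cell sampled at the grid times."""
    seeds = np.array([rng_seed], dtype=np.int64)
    rho = np.array([params.rho_u])
    counts = _kernels.ssa_cells(
        seeds, rho, params.b, params.d, params.sigma_b, params.sigma_u,
        time_grid.times,
    )
    return counts[0]


def simulate_population(
    params: Params,
    n_cells: int,
    time_grid: TimeGrid,
    k_max: int = 2,
    rng_seed: int = 0,
) -> tuple[SnapshotSample, MomentSeries]:
    """Simulate ``n_cells`` independent cells and their population moments.

    Returns the raw counts and the central moments up to order ``k_max``.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells for population moments")
    if not 1 <= k_max <= 6:
        raise ValueError("k_max must be in 1..6")
    seeds = _cell_seeds(rng_seed, n_cells)
    if isinstance(params, HeterogeneousParams):
        mu, sig = params.lognormal_log_params()
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 1)))
        rho = np.exp(mu + sig * rng.standard_normal(n_cells))
        b, d, sb, su = params.b, params.d, params.sigma_b, params.sigma_u
    else:
        rho = np.full(n_cells, params.rho_u)
        b, d, sb, su = params.b, params.d, params.sigma_b, params.sigma_u
    counts = _kernels.ssa_cells(seeds, rho, b, d, sb, su, time_grid.times)
    sample = SnapshotSample(counts, time_grid.times, params=params, seed=rng_seed)
    return sample, sample.central_moments(k_max)


def add_measurement_noise(
    sample: SnapshotSample, noise_scale: float, rng_seed: int = 0
) -> SnapshotSample:
    """Multiplicative lognormal measurement noise with unit median.

    Each measurement is multiplied by ``exp(eps)`` with
    ``eps ~ N(0, noise_scale^2)`` independently, emulating calibration and
    detection noise on fluorescence readouts.  ``noise_scale = 0`` returns an
    identical copy.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return SnapshotSample(
            sample.counts.copy(), sample.times, sample.params, sample.seed
        )
    rng = np.random.default_rng(rng_seed)
    factors = np.exp(noise_scale * rng.standard_normal(sample.counts.shape))
    return SnapshotSample(
        sample.counts * factors, sample.times, sample.params, sample.seed
    )
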