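"""Central-moment containers and their CSV interchange format.

A :class:`MomentSeries` holds central moments of the protein copy number on a
time grid: order 1 is the mean, order ``k >= 2`` the ``k``-th central moment
``(1/N) sum_i (x_i - mean)^k`` (population normalisation throughout).  The
``source`` tag records provenance: ``sample`` (finite-N data), ``fsp``
(master-equation ground truth) or ``closure`` (moment-closure prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["MomentSeries", "sample_central_moments"]


@dataclass
class MomentSeries:
    """Central moments ``mu_k(t_l)`` for orders ``1..K`` on a time grid.

    ``values[k-1, l]`` is the order-``k`` central moment at time ``times[l]``.
    """

    times: np.ndarray
    values: np.ndarray
    source: str = "sample"
    n_cells: Optional[int] = None
    flagged: bool = False  # closure predictions: negative variance / blow-up

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.times.size:
            raise ValueError(
                f"values shape {self.values.shape} incompatible with "
                f"{self.times.size} time points"
            )

    @property
    def K(self) -> int:
        """Highest moment order available."""
        return self.values.shape[0]

    @property
    def L(self) -> int:
        return self.times.size

    def order(self, k: int) -> np.ndarray:
        """Time series of the order-``k`` central moment."""
        if not 1 <= k <= self.K:
            raise ValueError(f"order {k} not available (K={self.K})")
        return self.values[k - 1]

    def truncated(self, k_max: int) -> "MomentSeries":
        """Copy keeping only orders ``1..k_max``."""
        if k_max > self.K:
            raise ValueError(f"cannot truncate to {k_max} > K={self.K}")
        return MomentSeries(
            self.times, self.values[:k_max].copy(), self.source,
            self.n_cells, self.flagged,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = self.n_cells if self.n_cells is not None else ""
        for k in range(1, self.K + 1):
            for l, t in enumerate(self.times):
                rows.append((t, k, self.values[k - 1, l], n, self.source))
        return pd.DataFrame(
            rows, columns=["time", "order", "value", "n_cells", "source"]
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MomentSeries":
        df = pd.read_csv(path)
        times = np.sort(df["time"].unique())
        orders = np.sort(df["order"].unique())
        if not np.array_equal(orders, np.arange(1, orders.size + 1)):
            raise ValueError("moment CSV must contain contiguous orders 1..K")
        values = np.empty((orders.size, times.size))
        piv = df.pivot_table(index="order", columns="time", values="value")
        values[:] = piv.loc[orders, times].to_numpy()
        n_cells = None
        if "n_cells" in df and df["n_cells"].notna().any():
            raw = df["n_cells"].dropna()
            if len(raw) and str(raw.iloc[0]).strip() != "":
                n_cells = int(float(raw.iloc[0]))
        source = str(df["source"].iloc[0]) if "source" in df else "sample"
        return cls(times, values, source=source, n_cells=n_cells)


def sample_central_moments(counts: np.ndarray, k_max: int) -> np.ndarray:
    """Sample central moments of orders ``1..k_max`` for one time point.

    ``counts`` is the vector of per-cell protein numbers.  The mean and the
    central moments ``(1/N) sum_i (x_i - mean)^k`` use the population (1/N)
    normalisation.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a nonempty 1-D array")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    out = np.empty(k_max)
    mean = x.mean()
    out[0] = mean
    if k_max > 1:
        dev = x - mean
        p = dev.copy()
        for k in range(2, k_max + 1):
            p *= dev
            out[k - 1] = p.mean()
    return out
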