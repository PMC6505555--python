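"""Negative auto-regulatory transcriptional feedback loop: model definition.

The circuit is a single-copy gene that switches between an active state ``G``
(ON) and a repressed state ``G*`` (OFF).  While ON, proteins are produced in
geometric translational bursts; the protein itself represses the gene by
binding to it.  Reactions (propensities in parentheses)::

    G  -> G + m P   (rho_u, burst size m ~ psi)
    G + P -> G*     (sigma_b * n, gene ON)
    G* -> G         (sigma_u)
    P  -> 0         (d * n)

with the geometric burst-size distribution ``psi(m) = b^m / (1+b)^(m+1)``,
``m = 0, 1, 2, ...`` whose mean is the mean burst size ``b``.  mRNA is not
modelled explicitly: in the fast mRNA-decay limit its effect is exactly the
geometric protein burst.

Units are nondimensional; time is conveniently measured in units of the
protein lifetime ``1/d`` (the study parameter sets use ``d = 1``).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Union

import numpy as np

__all__ = [
    "GeneState",
    "FeedbackLoopParams",
    "HeterogeneousParams",
    "TimeGrid",
    "burst_pmf",
    "burst_raw_moments",
    "Reaction",
    "reaction_network",
]


class GeneState(enum.Enum):
    """Promoter state: ON (``G``, transcribing) or OFF (``G*``, repressed)."""

    ON = 1
    OFF = 0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FeedbackLoopParams:
    """Kinetic parameters of the feedback loop for a population of identical cells.

    Attributes
    ----------
    rho_u : float
        Burst-firing (protein production) rate in the ON state [1/time].
    b : float
        Mean protein burst size (mean of the geometric burst distribution).
    d : float
        Protein degradation rate [1/time].
    sigma_b : float
        Protein-DNA binding rate [1/(molecule * time)].
    sigma_u : float
        Unbinding (OFF -> ON) rate [1/time].
    """

    rho_u: float
    b: float
    d: float
    sigma_b: float
    sigma_u: float

    def __post_init__(self) -> None:
        _require_positive(
            rho_u=self.rho_u, b=self.b, d=self.d,
            sigma_b=self.sigma_b, sigma_u=self.sigma_u,
        )

    def as_array(self) -> np.ndarray:
        """Parameter vector ``(rho_u, b, d, sigma_b, sigma_u)``."""
        return np.array(
            [self.rho_u, self.b, self.d, self.sigma_b, self.sigma_u], dtype=float
        )

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "FeedbackLoopParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {theta.shape}")
        return cls(*theta)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "FeedbackLoopParams":
        p = Path(source)
        text = p.read_text() if p.is_file() else str(source)
        return cls(**json.loads(text))


@dataclass(frozen=True)
class HeterogeneousParams:
    """Parameters for a non-identical cell population.

    The burst-firing rate ``rho_u`` varies from cell to cell following a
    lognormal law; all other rates are shared.  ``rho_u_scale`` selects the
    convention for (``mean_rho_u``, ``sd_rho_u``):

    - ``"arithmetic"`` (default): mean and standard deviation of ``rho_u``
      itself.
    - ``"log"``: ``mean_rho_u`` is the median (``exp`` of the log-location)
      and ``sd_rho_u`` the log-scale sigma, so ``sd_rho_u`` is approximately
      the cell-to-cell coefficient of variation.
    """

    mean_rho_u: float
    sd_rho_u: float
    b: float
    d: float
    sigma_b: float
    sigma_u: float
    rho_u_scale: str = "arithmetic"

    def __post_init__(self) -> None:
        _require_positive(
            mean_rho_u=self.mean_rho_u, b=self.b, d=self.d,
            sigma_b=self.sigma_b, sigma_u=self.sigma_u,
        )
        if self.sd_rho_u < 0 or not math.isfinite(self.sd_rho_u):
            raise ValueError("sd_rho_u must be >= 0")
        if self.rho_u_scale not in ("arithmetic", "log"):
            raise ValueError("rho_u_scale must be 'arithmetic' or 'log'")

    def lognormal_log_params(self) -> tuple[float, float]:
        """Location/scale ``(mu, sigma)`` of ``ln rho_u``.

        ``sd_rho_u = 0`` degenerates to a point mass at ``mean_rho_u``.
        """
        if self.rho_u_scale == "log":
            return math.log(self.mean_rho_u), self.sd_rho_u
        if self.sd_rho_u == 0.0:
            return math.log(self.mean_rho_u), 0.0
        cv2 = (self.sd_rho_u / self.mean_rho_u) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.mean_rho_u) - 0.5 * sigma2
        return mu, math.sqrt(sigma2)

    def as_array(self) -> np.ndarray:
        """Vector ``(mean_rho_u, sd_rho_u, b, d, sigma_b, sigma_u)``."""
        return np.array(
            [self.mean_rho_u, self.sd_rho_u, self.b, self.d,
             self.sigma_b, self.sigma_u], dtype=float,
        )

    @classmethod
    def from_array(
        cls, theta: np.ndarray, rho_u_scale: str = "arithmetic"
    ) -> "HeterogeneousParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {theta.shape}")
        return cls(*theta, rho_u_scale=rho_u_scale)

    def homogeneous(self) -> FeedbackLoopParams:
        """Identical-cell parameter set with ``rho_u = mean_rho_u``."""
        return FeedbackLoopParams(
            self.mean_rho_u, self.b, self.d, self.sigma_b, self.sigma_u
        )

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "HeterogeneousParams":
        p = Path(source)
        text = p.read_text() if p.is_file() else str(source)
        return cls(**json.loads(text))


Params = Union[FeedbackLoopParams, HeterogeneousParams]


def load_params(source: Union[str, Path]) -> Params:
    """Load either parameter variant from a JSON file or string."""
    p = Path(source)
    text = p.read_text() if p.is_file() else str(source)
    data = json.loads(text)
    if "mean_rho_u" in data:
        return HeterogeneousParams(**data)
    return FeedbackLoopParams(**data)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing nonnegative measurement times ``t_1 < ... < t_L``."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def L(self) -> int:
        return self.times.size

    @classmethod
    def default(cls, t_max: float = 30.0, dt: float = 1.0) -> "TimeGrid":
        """The study's default snapshot grid ``t = 1, 2, ..., 30``."""
        n = int(round(t_max / dt))
        return cls(dt * np.arange(1, n + 1))


# ---------------------------------------------------------------------------
# Geometric burst-size distribution


def burst_pmf(b: float, m) -> np.ndarray:
    """Geometric burst-size pmf ``psi(m) = b^m / (1+b)^(m+1)``, ``m >= 0``.

    Evaluated in log-space so large ``m`` does not overflow.
    """
    if not b > 0:
        raise ValueError("mean burst size b must be > 0")
    m_arr = np.asarray(m)
    if np.any(m_arr < 0) or np.any(m_arr != np.floor(m_arr)):
        raise ValueError("burst size m must be a nonnegative integer")
    logp = m_arr * math.log(b) - (m_arr + 1.0) * math.log1p(b)
    out = np.exp(logp)
    return out if out.shape else float(out)


def burst_raw_moments(b: float, k: int = 3) -> np.ndarray:
    """Exact raw moments ``E[m^j], j = 1..k`` of the geometric burst law.

    Closed forms via falling-factorial moments ``E[m(m-1)...(m-j+1)] = j! b^j``:

    - ``E[m]   = b``
    - ``E[m^2] = 2 b^2 + b``
    - ``E[m^3] = 6 b^3 + 6 b^2 + b``
    - ``E[m^4] = 24 b^4 + 36 b^3 + 14 b^2 + b``
    """
    if not b > 0:
        raise ValueError("mean burst size b must be > 0")
    if not 1 <= k <= 4:
        raise ValueError("moment order k must be in 1..4")
    full = np.array(
        [
            b,
            2 * b**2 + b,
            6 * b**3 + 6 * b**2 + b,
            24 * b**4 + 36 * b**3 + 14 * b**2 + b,
        ]
    )
    return full[:k]


# ---------------------------------------------------------------------------
# Reaction network (reference definition; the SSA kernel mirrors it)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a propensity rule and a state update.

    ``propensity(gene_on, n)`` evaluates the channel's rate at state
    ``(gene_on, n)``; ``apply(gene_on, n, rng)`` returns the post-firing state
    (the production channel draws its burst size from ``psi``).
    """

    name: str
    propensity: Callable[[bool, int], float]
    apply: Callable[[bool, int, np.random.Generator], tuple[bool, int]]


def reaction_network(params: FeedbackLoopParams) -> list[Reaction]:
    """The four reaction channels of the feedback loop.

    This is the reference (pure-Python) definition used by tests and by the
    documentation; the production SSA is the compiled kernel in
    :mod:`mominf._kernels`, which implements the same channels.
    """
    r, b, d, sb, su = params.as_array()
    q = b / (1.0 + b)  # geometric success parameter, P(m >= k) = q^k

    def prod_apply(g, n, rng):
        # geometric on {0, 1, ...} with mean b
        m = int(rng.geometric(1.0 - q)) - 1
        return g, n + m

    return [
        Reaction(
            "bursty_production",
            lambda g, n: r if g else 0.0,
            prod_apply,
        ),
        Reaction(
            "binding",
            lambda g, n: sb * n if g else 0.0,
            lambda g, n, rng: (False, n - 1),
        ),
        Reaction(
            "unbinding",
            lambda g, n: 0.0 if g else su,
            lambda g, n, rng: (True, n),
        ),
        Reaction(
            "decay",
            lambda g, n: d * n,
            lambda g, n, rng: (g, n - 1),
        ),
    ]
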