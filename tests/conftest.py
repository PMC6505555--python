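import numpy as np
import pytest
from hypothesis import settings

from mominf import FeedbackLoopParams, TimeGrid, fsp_moments, fsp_solve

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# reference parameter set used throughout the synthetic studies
FIG1 = np.array([13.0, 3.0, 1.0, 0.001, 0.1])


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid.default()


@pytest.fixture(scope="session")
def fig1_params() -> FeedbackLoopParams:
    return FeedbackLoopParams(*FIG1)


@pytest.fixture(scope="session")
def fsp_fig1(grid, fig1_params):
    """Master-equation moments (orders 1..6) at the reference parameters."""
    return fsp_moments(fsp_solve(fig1_params, grid), 6)


@pytest.fixture(scope="session")
def fsp_b10(grid):
    """Master-equation moments at the large-burst (b=10) parameter set."""
    return fsp_moments(
        fsp_solve(FeedbackLoopParams(13, 10, 1, 0.001, 0.1), grid), 6
    )
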