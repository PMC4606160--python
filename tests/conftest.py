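import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from beliefgrid import (
    DEFAULT_GRID,
    DEFAULT_MAPPING,
    make_grid,
    simulate_participant,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    """The 148-bin contrast grid used for belief estimation."""
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def mapping():
    return DEFAULT_MAPPING


@pytest.fixture(scope="session")
def toy_grid():
    """Small 10-bin grid for brute-force oracle comparisons."""
    return make_grid(0.0, 10.0, 1.0)


@pytest.fixture(scope="session")
def bayes_trials():
    """One simulated Bayesian participant (sigma=13, 6 blocks)."""
    return simulate_participant(1, agent="bayesian", sigma=13.0, n_blocks=6, seed=11)


@pytest.fixture(scope="session")
def wsls_trials():
    """One simulated WSLS participant (sigma=8, 6 blocks)."""
    return simulate_participant(2, agent="wsls", sigma=8.0, n_blocks=6, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
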