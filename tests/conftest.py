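import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dnmodel import TimeGrid, step_stimulus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def epoch_grid():
    """The standard 1.2 s trial epoch at 1 kHz."""
    return TimeGrid(dt=0.001, n=1200)


@pytest.fixture(scope="session")
def step_500(epoch_grid):
    """A 500 ms full-contrast stimulus in the standard epoch."""
    return step_stimulus(0.5, epoch_grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
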