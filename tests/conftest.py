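import numpy as np
import pytest

from bcaapet import (
    FrameSchedule,
    KineticParameters,
    default_grid,
    default_input_function,
)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.canonical()


@pytest.fixture(scope="session")
def feng():
    return default_input_function()


@pytest.fixture(scope="session")
def grid(schedule):
    return default_grid(schedule)


@pytest.fixture(scope="session")
def scv_params():
    """Supraclavicular-like parameter set used throughout the examples."""
    return KineticParameters(K1=0.05, k2=0.4, k3=0.08, vb=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
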