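import numpy as np
import pytest

from depthpop.core import SimConfig


@pytest.fixture(scope="session")
def tiny_sim() -> SimConfig:
    """Smallest config that still exercises every cell class."""
    return SimConfig(duration_s=60.0, n_depth=3, n_choice=3, n_place=3,
                     n_noise=3, n_trials=8)


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    return SimConfig(duration_s=120.0, n_depth=6, n_choice=6, n_place=6,
                     n_noise=12, n_trials=15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
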