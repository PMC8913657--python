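import numpy as np
import pytest

from stemfit import FrequencyGrid, get_preset, make_grid


@pytest.fixture(scope="session")
def grid_241() -> FrequencyGrid:
    """Default 100 Hz - 100 kHz sweep at 80 points/decade."""
    return make_grid(100.0, 100_000.0, 80)


@pytest.fixture(scope="session")
def marjoram5_cole():
    return get_preset("cole", "marjoram5")


def single_freq_grid(f_hz: float) -> FrequencyGrid:
    return FrequencyGrid(frequencies=np.array([f_hz]), points_per_decade=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
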