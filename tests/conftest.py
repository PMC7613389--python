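import numpy as np
import pytest

from chimetraits.rtm import SurrogateRTM
from chimetraits.sampling import build_lut, default_sampling_config
from chimetraits.sensor import apply_water_vapour_mask, chime_band_grid
from chimetraits.spectra import default_grid


@pytest.fixture(scope="session")
def rtm():
    return SurrogateRTM()


@pytest.fixture(scope="session")
def band_grid():
    """Default CHIME-like configuration: 210 bands, 157 retained."""
    return apply_water_vapour_mask(chime_band_grid())


@pytest.fixture(scope="session")
def sim_grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_lut(rtm, band_grid):
    """A 60-record noiseless LUT shared by regression-stage tests."""
    return build_lut(default_sampling_config(n_samples=60, seed=11), rtm, band_grid)
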