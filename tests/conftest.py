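import numpy as np
import pytest

from muadecode.waveforms import (CellType, PopulationConfig,
                                 default_waveform_library, make_waveform,
                                 sample_population)

FS = 20_000.0


@pytest.fixture(scope="session")
def msn_template():
    return make_waveform(CellType.MSN, 300e-6, 120.0, FS)


@pytest.fixture(scope="session")
def fsi_template():
    return make_waveform(CellType.FSI, 150e-6, 80.0, FS)


@pytest.fixture(scope="session")
def library():
    return default_waveform_library(seed=0)


@pytest.fixture(scope="session")
def small_population(library):
    """2,000-cell population with the default type mix and rates."""
    return sample_population(PopulationConfig(n_cells=2000, seed=7), library)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
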