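import numpy as np
import pytest

from hrmelt import io as hio
from hrmelt.melt_model import Baselines, NoiseModel, TemperatureGrid

ASSAY_NAMES = ("RET", "PAX2", "ALDH1A2")


@pytest.fixture(scope="session")
def grid():
    return TemperatureGrid()


@pytest.fixture(scope="session")
def baselines():
    return Baselines()


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel.zero()


@pytest.fixture(scope="session")
def assays():
    return {name: hio.packaged_assay(name) for name in ASSAY_NAMES}


@pytest.fixture(scope="session")
def ret(assays):
    return assays["RET"]


@pytest.fixture(scope="session")
def aldh1a2(assays):
    return assays["ALDH1A2"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
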