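import numpy as np
import pytest

from lumensor import (
    NOISELESS_PHOTOPHYSICS,
    PhotophysicsModel,
    SensorKinetics,
)


@pytest.fixture(scope="session")
def kinetics() -> SensorKinetics:
    return SensorKinetics()


@pytest.fixture(scope="session")
def photophysics() -> PhotophysicsModel:
    return PhotophysicsModel()


@pytest.fixture(scope="session")
def noiseless() -> PhotophysicsModel:
    return NOISELESS_PHOTOPHYSICS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
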