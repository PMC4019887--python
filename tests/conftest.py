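import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from probfab.circuit_rng import BernoulliUnit, NoiseModel, calibrate_threshold


@pytest.fixture(scope="session")
def noise() -> NoiseModel:
    return NoiseModel()


@pytest.fixture(scope="session")
def fair_unit(noise) -> BernoulliUnit:
    return BernoulliUnit(noise, calibrate_threshold(0.5, noise))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)
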