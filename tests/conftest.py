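import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from seedphys.simulate import (
    BiochemParams,
    GrowthParams,
    SyntheticScenario,
    WeatherParams,
    YieldParams,
)


@pytest.fixture
def scenario():
    return SyntheticScenario(seed=123)


@pytest.fixture
def noiseless_scenario():
    return SyntheticScenario(
        seed=123,
        weather=WeatherParams(temp_noise_sd=0.0, srad_noise_sd=0.0),
        growth=GrowthParams(noise_sd=0.0),
        yields=YieldParams(replicate_cv=0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
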