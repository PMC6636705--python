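import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laminaprobe.simulate import (
    CellSimConfig,
    MotoneuronPool,
    MotoneuronPoolConfig,
    simulate_population_spikes,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")





@pytest.fixture(scope="session")
def default_spikes():
    """24 simulated layer-5 cells at the default in vitro calibration."""
    return simulate_population_spikes(CellSimConfig(), 24, seed=0)


@pytest.fixture(scope="session")
def default_pool():
    """One realized motoneuron pool at the default calibration."""
    return MotoneuronPool(MotoneuronPoolConfig(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
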