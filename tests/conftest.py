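import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import heatsmoke as hs

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    return hs.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def environment(sim_config):
    return hs.generate_environment(sim_config)


@pytest.fixture(scope="session")
def exposure_series(environment):
    """(series, thresholds) for the session's synthetic world."""
    return hs.build_exposure_series(
        environment.tmax,
        environment.pm25,
        environment.plumes,
        environment.crosswalk,
    )


@pytest.fixture(scope="session")
def cases(sim_config, exposure_series):
    series, _ = exposure_series
    return hs.simulate_cases(sim_config, series)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
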