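import pytest
from hypothesis import settings

from gasmasim.config import load_config
from gasmasim.environment import Environment
from gasmasim.geometry import BeamFootprint, CapillaryArray

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_array() -> CapillaryArray:
    return CapillaryArray()


@pytest.fixture(scope="session")
def default_beam() -> BeamFootprint:
    return BeamFootprint()


@pytest.fixture(scope="session")
def nominal_env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def noiseless_config():
    """Defaults with the noise and chamber drift switched off."""
    return load_config(
        overrides={
            "simulation": {"noise_sd": 0.0},
            "design": {"set1_drift_enabled": False, "set2_drift_enabled": False},
        }
    )
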