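import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epodyn as ed

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_patient() -> ed.PatientParameters:
    return ed.make_default_patient()


@pytest.fixture(scope="session")
def default_steady(default_patient) -> ed.SpectralState:
    return ed.steady_state(default_patient)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
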