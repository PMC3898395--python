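import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glucofet import (
    DeviceGeometry,
    GlucoseResponseLaw,
    SensingCondition,
    TransportParams,
    derive_params,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    return DeviceGeometry()


@pytest.fixture
def transport():
    return TransportParams()


@pytest.fixture
def derived(geometry, transport):
    return derive_params(geometry, transport)


@pytest.fixture
def law():
    return GlucoseResponseLaw()


@pytest.fixture
def pbs_condition():
    """Buffer only, no glucose (the F_g = 0 reference condition)."""
    return SensingCondition(pbs_concentration=1.0, pbs_voltage=0.6, glucose_concentration=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
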