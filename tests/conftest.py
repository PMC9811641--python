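import math

import pytest
from hypothesis import HealthCheck, settings

from cavibridge.materials import BridgeGeometry, JetSpec, load_materials

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def materials():
    return load_materials()


@pytest.fixture(scope="session")
def water(materials):
    return materials["water"]


@pytest.fixture
def jet():
    return JetSpec(rho_0=1000.0, D_0=100e-6, U_0=20.0)


@pytest.fixture
def geometry():
    return BridgeGeometry()
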