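import numpy as np
import pytest

from embryowet.wetting import ConfinementGeometry
from embryowet.synthetic import DEFAULT_GEOMETRY, DEFAULT_TENSION


@pytest.fixture(scope="session")
def crypt():
    """Default funnel-shaped crypt used across the suite."""
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def cylinder50():
    return ConfinementGeometry.cylinder(50.0)


@pytest.fixture(scope="session")
def tension_truth():
    return DEFAULT_TENSION


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
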