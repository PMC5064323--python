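import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cascadenet import LayerGeometry, ModelParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params200():
    """Reduced-resolution parameter set used for simulation-heavy tests."""
    return ModelParams(N=200)


@pytest.fixture(scope="session")
def params64():
    """Very small network for fast dynamical checks."""
    return ModelParams(N=64)


@pytest.fixture()
def geometry64(params64):
    return LayerGeometry.from_params(params64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160)
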