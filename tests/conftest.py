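import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methylcall.synthetic_data import make_pore_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def k3_model():
    """Small k=3 pore model used by most HMM unit tests."""
    return make_pore_model(k=3, m_shift=4.0, seed=0)


@pytest.fixture(scope="session")
def k6_model():
    return make_pore_model(k=6, m_shift=4.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
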