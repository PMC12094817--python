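import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairflow.synthetic_data import ToyWorldParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_world() -> ToyWorldParams:
    """2 hidden states, 2+2 non-mask tokens: 16 outcomes at N=2."""
    return ToyWorldParams.default(n_hidden=2, n_seq_tokens=2, n_struct_tokens=2)


@pytest.fixture(scope="session")
def small_world() -> ToyWorldParams:
    """2 hidden states, 3+3 non-mask tokens: 729 outcomes at N=3."""
    return ToyWorldParams.default(n_hidden=2, n_seq_tokens=3, n_struct_tokens=3)


@pytest.fixture(scope="session")
def default_world() -> ToyWorldParams:
    return ToyWorldParams.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
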