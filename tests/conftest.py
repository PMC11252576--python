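import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def defaults():
    """Reference parameters, rate matrix and initial state."""
    from fracad import as_matrix, default_initial_state, default_parameters

    params = default_parameters()
    return params, as_matrix(params), default_initial_state()


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)
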