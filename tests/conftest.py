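import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_instance():
    """One modest coupled instance shared by read-only tests."""
    from mprnmf import generate_instance

    return generate_instance(
        n_l=20, n_g=40, n_o=12, planted_k=3, noise=0.1, mask_fraction=0.2, seed=7
    )
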