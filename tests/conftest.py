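import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study shared by the io/pipeline tests."""
    from streakmorph import generate_bundle

    return generate_bundle(seed=7, n_traces_per_animal=2, n_proteins=120, n_planted=8)
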