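import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic trial at the shipped default configuration."""
    from manuresub import default_config, generate_trial

    return generate_trial(default_config(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A trial without the community table, for fast table-level tests."""
    from manuresub import default_config, generate_trial

    return generate_trial(default_config(seed=7), include_community=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
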