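import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from terramotif import CategoryConfig, SyntheticConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort_config():
    """A down-scaled cohort with the same structure as the reference study
    conditions: two categories with a 3x TERRA-fraction contrast."""
    return SyntheticConfig(
        categories={
            "ground": CategoryConfig(n_samples=3, terra_fraction=0.01),
            "space_effect": CategoryConfig(n_samples=3, terra_fraction=0.03),
        },
        reads_per_sample=800,
        read_length=80,
        seed=42,
    )
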