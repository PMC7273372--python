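import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enzid.simulate import EnrichedPair, GeneratorConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small strongly-enriched two-class dataset for classifier tests."""
    cfg = GeneratorConfig(
        n_pos=25,
        n_neg=25,
        length_range=(60, 120),
        enriched_pairs=(EnrichedPair("A", "A", 3, 0.3), EnrichedPair("L", "L", 3, 0.3)),
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
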