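import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def random_dna(rng):
    def make(length: int, gc: float = 50.0) -> str:
        from genefishkit.simulate import random_gene

        return random_gene(length, gc, np.random.default_rng(rng.integers(2**31)))

    return make
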