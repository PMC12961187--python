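import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_dna(rng):
    bases = np.array(list("ACGT"))

    def make(length: int) -> str:
        return "".join(rng.choice(bases, size=length))

    return make
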