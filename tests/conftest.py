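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

from phagecensor import SequenceMultiset


@pytest.fixture
def toy_multiset() -> SequenceMultiset:
    """The four-element toy library {A(1) B(2) C(3) D(4)} (as DNA codons)."""
    return SequenceMultiset(["AAA", "CCC", "GGG", "TTT"], np.array([1, 2, 3, 4]))


@pytest.fixture(scope="session")
def ramp_multiset() -> SequenceMultiset:
    """1000 unique random inserts with copy numbers 1..1000 (total 500,500)."""
    from phagecensor.synthetic import _random_inserts

    rng = np.random.default_rng(2024)
    return SequenceMultiset(_random_inserts(1000, rng), np.arange(1, 1001))
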