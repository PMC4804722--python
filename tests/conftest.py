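import numpy as np
import pytest

from tfclust import FixtureSpec, make_fixture
from tfclust.pwm import PWM


def small_spec(seed: int = 5) -> FixtureSpec:
    """A reduced fixture whose planting demand fits capacity for any seed."""
    return FixtureSpec(
        seed=seed,
        n_genes=80,
        de_genes_per_stage=14,
        n_two_stage_de=3,
        n_hubs=2,
        partners_per_hub=(3, 4),
        pair_frequency=(4, 6),
    )


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture(small_spec())


@pytest.fixture(scope="session")
def default_fixture():
    return make_fixture(FixtureSpec(seed=11))


def word_pwm(word: str, pwm_id: str = "M", weight: float = 10.0) -> PWM:
    """A near-deterministic PWM whose consensus is the given word."""
    counts = np.ones((len(word), 4))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, c in enumerate(word):
        counts[i, idx[c]] = weight
    return PWM(id=pwm_id, counts=counts, pseudocount=0.0)
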