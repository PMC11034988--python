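import numpy as np
import pytest

from strobekit.encoding import encode
from strobekit.simulate import RepeatSimParams, simulate_random, simulate_repetitive


def random_dna(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def random_seq_600():
    return encode(simulate_random(600, rng_seed=11), "rand600")


@pytest.fixture(scope="session")
def random_seq_2k():
    return encode(simulate_random(2000, rng_seed=7), "rand2k")


@pytest.fixture(scope="session")
def small_repeat_seq():
    """Short tandem-repeat sequence with occasional substitutions."""
    s = simulate_repetitive(
        RepeatSimParams(unit_length=60, copies=20, sub_rate=0.05, flank_length=500, rng_seed=3)
    )
    return encode(s, "repeat")
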