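import numpy as np
import pytest

from dashkit.fixtures import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20160304)


@pytest.fixture
def random_seq():
    """Factory for seeded random DNA strings."""

    def _make(length, seed=0, gc=0.44):
        return random_dna(np.random.default_rng(seed), length, gc)

    return _make
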