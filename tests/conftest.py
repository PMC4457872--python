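import numpy as np
import pytest

from dcapipe.msa import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, M, L, gap_prob=0.1) -> Alignment:
    rows = rng.integers(1, 21, size=(M, L))
    rows[rng.random(size=(M, L)) < gap_prob] = 0
    return Alignment(ids=[f"seq{i}" for i in range(M)], rows=rows)


@pytest.fixture
def small_alignment(rng):
    return random_alignment(rng, M=20, L=30)
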