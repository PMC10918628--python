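import numpy as np
import pytest

from seqaug import OneHotBatch, encode


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_batch(rng) -> OneHotBatch:
    """Eight random 50-nt one-hot sequences."""
    return OneHotBatch(np.eye(4)[rng.integers(0, 4, size=(8, 50))])


@pytest.fixture
def tiny_batch() -> OneHotBatch:
    return encode(["ACGTAA", "TTGACA", "GGGCCC"])


def random_batch(n: int, length: int, seed: int = 0) -> OneHotBatch:
    r = np.random.default_rng(seed)
    return OneHotBatch(np.eye(4)[r.integers(0, 4, size=(n, length))])
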