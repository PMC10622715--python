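import numpy as np
import pytest

from optinalysis import encode_sequence

DNA_REF = "CTAGCTAGCTAG"
PROT_REF = "GASPCLDQMFRY"


@pytest.fixture
def rng():
    return np.random.default_rng(20230101)


@pytest.fixture
def worked_pair():
    """The hand-calculated six-base aligned pair and its encodings."""
    a, b = "ATC-TA", "A-G-TA"
    return a, b, encode_sequence(a), encode_sequence(b)


def random_structures(rng, n_pairs, n_min=2, n_max=20, low=1.0, high=200.0):
    """Random positive-valued structure pairs (mass-like, non-degenerate)."""
    for _ in range(n_pairs):
        n = int(rng.integers(n_min, n_max + 1))
        yield rng.uniform(low, high, n).tolist(), rng.uniform(low, high, n).tolist()
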