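import numpy as np
import pytest

from stallseq.linkage import LibraryIndex
from stallseq.reporter_library import CodonPairInsert, enumerate_codon_pairs


@pytest.fixture(scope="session")
def dicodon_pool():
    return enumerate_codon_pairs()


@pytest.fixture(scope="session")
def pool_index(dicodon_pool):
    return LibraryIndex(dicodon_pool)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_library():
    """A handful of inserts with distinct, well-separated sequences."""
    pairs = [("AAA", "AAA"), ("GTG", "AAG"), ("AGA", "CAC"), ("AGC", "TTC"), ("GGC", "GGC")]
    return [CodonPairInsert.from_pair(c1, c2) for c1, c2 in pairs]
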