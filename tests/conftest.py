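import numpy as np
import pytest

from strandsym.kmer_core import KmerTable

# Reference dinucleotide rearrangement (frequency-sorted input, expected
# pair-adjacent output, and worst-case input reaching both maxima).
A1_2_WORDS = "AG CT AT GC AA CA TG GT CG AC TC CC GA TT GG TA".split()
A2_2_WORDS = "AG CT AT GC AA TT CA TG GT AC CG TC GA CC GG TA".split()
WORST_CASE_2 = "AA AC AG CA CC GA AT CG GC TA TC GG TG CT GT TT".split()


def table_from_ranked(words: list[str]) -> KmerTable:
    """Count table with strictly decreasing counts in the given word order,
    so that the frequency sort reproduces exactly that arrangement."""
    n = len(words)
    counts = {w: n - i for i, w in enumerate(words)}
    total = sum(counts.values())
    return KmerTable(k=len(words[0]), counts=counts, n_windows=total, n_valid=total)


def random_table(k: int, rng: np.random.Generator, max_count: int = 20) -> KmerTable:
    arr = rng.integers(0, max_count + 1, size=4**k)
    return KmerTable.from_dense(k, arr.astype(np.int64))


@pytest.fixture
def a1_reference() -> list[str]:
    return list(A1_2_WORDS)


@pytest.fixture
def a2_reference() -> list[str]:
    return list(A2_2_WORDS)


@pytest.fixture
def worst_case() -> list[str]:
    return list(WORST_CASE_2)
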