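import itertools

import numpy as np
import pytest

from domhier import WinLossMatrix


def perfect_linear_matrix(n: int = 12, wins_per_dyad: int = 1) -> WinLossMatrix:
    """Upper-triangular matrix: every individual beats all lower-ranked ones."""
    counts = wins_per_dyad * np.triu(np.ones((n, n), dtype=int), k=1)
    return WinLossMatrix(ids=[f"i{k:02d}" for k in range(n)], counts=counts)


def tournament_from_bits(n: int, bits: int) -> WinLossMatrix:
    """Complete binary tournament on n individuals encoded by dyad bits.

    Bit k of ``bits`` decides the k-th upper-triangle dyad (1 = row wins).
    Enumerating bits over range(2**(n*(n-1)//2)) yields every tournament.
    """
    counts = np.zeros((n, n), dtype=int)
    for k, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        if bits >> k & 1:
            counts[i, j] = 1
        else:
            counts[j, i] = 1
    return WinLossMatrix(ids=[str(i) for i in range(n)], counts=counts)


def random_count_matrix(
    n: int, rng: np.random.Generator, max_count: int = 5
) -> WinLossMatrix:
    counts = rng.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(counts, 0)
    return WinLossMatrix(ids=[str(i) for i in range(n)], counts=counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
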