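import numpy as np
import pytest

from coocc.community import CommunityMatrix, StratumKey


@pytest.fixture
def key():
    return StratumKey(2011, "LHW", "bulrush", "trophic", "predator")


@pytest.fixture
def abc_matrix(key):
    """Three-taxon matrix with hand-computable checkerboard units.

    Pairs: (A,B): r=2,2,S=0 -> CU 4; (A,C): r=2,2,S=1 -> CU 1;
    (B,C): r=2,2,S=1 -> CU 1.  C-score = 6/3 = 2.
    """
    return CommunityMatrix(
        key=key,
        taxa=["A", "B", "C"],
        sites=["s1", "s2", "s3", "s4"],
        cells=np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]]),
    )


@pytest.fixture
def checkerboard_2x2(key):
    return CommunityMatrix(
        key=key, taxa=["X", "Y"], sites=["s1", "s2"],
        cells=np.array([[1, 0], [0, 1]]),
    )


@pytest.fixture
def full_overlap(key):
    return CommunityMatrix(
        key=key, taxa=["A", "B", "C"], sites=["s1", "s2", "s3"],
        cells=np.ones((3, 3), dtype=int),
    )


def random_binary_matrix(rng, m, n, fill=0.5, nonzero_margins=True):
    cells = (rng.random((m, n)) < fill).astype(np.int8)
    if nonzero_margins:
        while (cells.sum(1) == 0).any() or (cells.sum(0) == 0).any():
            cells = (rng.random((m, n)) < fill).astype(np.int8)
    return cells


def brute_force_c_score(cells):
    """Counting oracle: CU(i,j) = number of ordered site pairs (a, b) with
    taxon i present only at a and taxon j present only at b."""
    cells = np.asarray(cells)
    m, n = cells.shape
    total = 0
    for i in range(m):
        for j in range(i + 1, m):
            cu = 0
            for a in range(n):
                for b in range(n):
                    if a == b:
                        continue
                    if (cells[i, a] == 1 and cells[j, a] == 0
                            and cells[j, b] == 1 and cells[i, b] == 0):
                        cu += 1
            total += cu
    return total / (m * (m - 1) / 2)
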