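import numpy as np
import pytest

from hic3d.io import BinTable, ContactMatrix
from hic3d.restraints import ScalingModel


@pytest.fixture
def bins5():
    return BinTable("chr1", 50_000, 5)


@pytest.fixture
def scaling():
    return ScalingModel()


@pytest.fixture
def decaying_matrix():
    """8-bin matrix with exact 1/|i-j| decay (constant diagonals)."""
    n = 8
    C = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = 1.0 / abs(i - j) if i != j else 2.0
    return ContactMatrix(BinTable("chr1", 50_000, n), C)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
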