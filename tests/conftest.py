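import numpy as np
import pytest

from cellcna.io_counts import BinGrid, CountMatrix
from cellcna.simulate import make_bingrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240102)


@pytest.fixture
def small_bingrid():
    """3 bins on one chromosome, flat tracks."""
    return BinGrid(np.array(["chr1"] * 3), np.array([0, 200_000, 400_000]),
                   np.array([200_000, 400_000, 600_000]),
                   np.full(3, 0.5), np.full(3, 1.0), 200_000)


@pytest.fixture
def two_chrom_bingrid():
    """Two chromosomes of 10 Mb each at 200 kb bins (100 bins total)."""
    return make_bingrid({"chr1": 10_000_000, "chr2": 10_000_000},
                        bin_size=200_000)


@pytest.fixture
def small_counts(small_bingrid):
    counts = np.array([[10, 20, 30], [40, 50, 60]])
    return CountMatrix(counts, ["cellA", "cellB"], small_bingrid)
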