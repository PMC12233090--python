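import numpy as np
import pytest

from scgt.io_preprocess import OmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ref():
    """3 genes x 4 cells labeled reference."""
    mat = np.array(
        [[5.0, 0.0, 2.0, 1.0],
         [1.0, 3.0, 0.0, 4.0],
         [0.0, 2.0, 6.0, 0.0]]
    )
    return OmicsDataset(
        matrix=mat,
        gene_ids=["A", "B", "C"],
        cell_ids=["r1", "r2", "r3", "r4"],
        labels=["T", "T", "B", "B"],
        modality="reference",
    )


@pytest.fixture
def tiny_query():
    """3 genes x 3 cells unlabeled query sharing genes B, C plus one extra."""
    mat = np.array(
        [[1.0, 0.0, 3.0],
         [0.0, 2.0, 1.0],
         [4.0, 1.0, 0.0]]
    )
    return OmicsDataset(
        matrix=mat,
        gene_ids=["B", "C", "D"],
        cell_ids=["q1", "q2", "q3"],
        labels=None,
        modality="query",
    )
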