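import numpy as np
import pytest
import scipy.sparse as sp

from proxeval import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(counts, labels=None, mito_mask=None, space="raw"):
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_names=np.array([f"g{j}" for j in range(g)], dtype=object),
        labels=None if labels is None else np.asarray(labels, dtype=object),
        mito_mask=mito_mask,
        space=space,
    )


@pytest.fixture
def toy_dataset():
    counts = [[5, 0, 1, 2],
              [0, 3, 0, 1],
              [2, 2, 2, 2],
              [0, 0, 4, 0]]
    return make_dataset(counts, labels=["a", "a", "b", "b"])
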