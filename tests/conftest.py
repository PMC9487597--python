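import numpy as np
import pytest

from screscale import CountMatrix, NormalizedMatrix, lognormalize, scale_genes


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 2 cells with mixed zero and nonzero entries."""
    return CountMatrix(
        values=np.array([[0.0, 1.0], [2.0, 0.0], [5.0, 5.0]]),
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2"],
        platform="plate",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def gaussian_scaled(rng):
    """A ScaledMatrix from random counts, for re-scaling property tests."""
    counts = rng.poisson(5.0, size=(40, 30)).astype(float) + 1.0
    cm = CountMatrix(
        values=counts,
        gene_ids=[f"g{i}" for i in range(40)],
        cell_ids=[f"c{j}" for j in range(30)],
    )
    return scale_genes(lognormalize(cm))


def two_blobs(rng, n_per=40, dim=5, sep=20.0):
    """Two well-separated Gaussian clouds plus labels."""
    a = rng.normal(0.0, 1.0, size=(n_per, dim))
    b = rng.normal(0.0, 1.0, size=(n_per, dim))
    b[:, 0] += sep
    x = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return x, labels
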