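import numpy as np
import pytest

from slle_sc2.core_manifold import LabeledExpressionMatrix


def make_matrix(values, labels=None, gene_prefix="g", sample_prefix="s"):
    """Wrap a raw array (samples x genes) into a LabeledExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    if labels is None:
        labels = np.array(["a"] * n)
    return LabeledExpressionMatrix(
        values=values,
        gene_ids=[f"{gene_prefix}{j}" for j in range(d)],
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        labels=np.asarray(labels),
    )


def random_two_class(rng, n_per_class=10, n_genes=6, shift=3.0):
    """Two Gaussian classes separated along the first gene axis."""
    n = 2 * n_per_class
    values = rng.normal(size=(n, n_genes))
    values[:n_per_class, 0] += shift
    labels = np.array(["pos"] * n_per_class + ["neg"] * n_per_class)
    return make_matrix(values, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class(rng):
    return random_two_class(rng)
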