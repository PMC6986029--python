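import numpy as np
import pytest

from normbench.counts_io import CountMatrix


def make_cm(counts, groups=None, prefix_g="g", prefix_s="s"):
    counts = np.asarray(counts)
    gene_ids = tuple(f"{prefix_g}{i}" for i in range(counts.shape[0]))
    sample_ids = tuple(f"{prefix_s}{j}" for j in range(counts.shape[1]))
    g = None
    if groups is not None:
        g = dict(zip(sample_ids, groups))
    return CountMatrix(gene_ids, sample_ids, counts, groups=g)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def random_counts(rng):
    """200 x 6 strictly positive random count matrix."""
    return make_cm(rng.integers(1, 500, size=(200, 6)))


@pytest.fixture
def nb_null_counts(rng):
    """400-gene NB null with 10 samples per group, dispersion 0.15."""
    G, n, phi = 400, 10, 0.15
    mu = rng.lognormal(np.log(50), 1.0, G)
    r = 1.0 / phi
    y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, 2 * n))
    return make_cm(y, groups=["A"] * n + ["B"] * n)
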