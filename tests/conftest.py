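import numpy as np
import pytest

from celltopics.data_io import CountLayer
from celltopics.graph_build import build_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_layer():
    """3 genes x 3 cells, one strong edge per cell (the 6-node toy graph)."""
    return CountLayer("toy", ["g1", "g2", "g3"], ["c1", "c2", "c3"], np.diag([3.0, 3.0, 3.0]))


@pytest.fixture
def toy_graph(toy_layer):
    return build_graph(toy_layer)


@pytest.fixture
def random_layer(rng):
    """A dense-ish random 10-gene x 8-cell integer layer."""
    counts = rng.poisson(2.0, size=(10, 8)).astype(float)
    counts[0, :] += 1  # keep every gene and cell connected
    counts[:, 0] += 1
    return CountLayer("rand", [f"g{i}" for i in range(10)], [f"c{j}" for j in range(8)], counts)


@pytest.fixture
def random_graph(random_layer):
    return build_graph(random_layer)


def make_bipartite(n_cells, n_genes, rate, seed, name="layer"):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate, size=(n_genes, n_cells)).astype(float)
    counts[0, :] += 1
    counts[:, 0] += 1
    return CountLayer(
        name, [f"{name}_g{i}" for i in range(n_genes)], [f"c{j}" for j in range(n_cells)], counts
    )
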