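import numpy as np
import pytest

from organtopo import synthetic


@pytest.fixture(scope="session")
def toy_organ():
    """One small annotated organ graph, shared across read-only tests."""
    return synthetic.generate_organ(synthetic.toy_spec(seed=1))


@pytest.fixture(scope="session")
def default_organ():
    """One full-scale organ graph (a few thousand cells)."""
    return synthetic.generate_organ(synthetic.default_spec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connected_graph(rng, n_min=5, n_max=30, p=0.25):
    """Random connected graph with areas, for oracle comparisons."""
    import networkx as nx

    while True:
        n = int(rng.integers(n_min, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() >= 3 and nx.is_connected(g):
            break
    for a, b in g.edges:
        g.edges[a, b]["area_um2"] = float(rng.uniform(0.5, 50.0))
    return g
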