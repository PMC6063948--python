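import networkx as nx
import numpy as np
import pytest

from netdim import SpatialGraph


@pytest.fixture
def path_graph():
    """Path a-b-c-d-e with unit weights."""
    g = nx.path_graph(["a", "b", "c", "d", "e"])
    nx.set_edge_attributes(g, 1.0, "weight")
    return SpatialGraph(g)


@pytest.fixture
def weighted_triangle():
    """Triangle with weights 1, 1, 5; apex 'a' joins the two unit edges."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("a", "c", weight=1.0)
    g.add_edge("b", "c", weight=5.0)
    return SpatialGraph(g, units="native")


def random_weighted_graph(n, p, seed, max_w=3.0):
    """Connected-ish random graph with random positive weights."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.1, max_w))
    return SpatialGraph(g, units="native")
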