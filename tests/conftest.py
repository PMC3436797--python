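import networkx as nx
import numpy as np
import pytest

from srmcl.graph import Network


def build_network(edges):
    """Network from (u, v) or (u, v, w) tuples."""
    return Network(edges=edges)


def random_network(n, p, seed, weighted=False):
    """Random Gnp graph as a Network; isolated nodes are discarded."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:  # degenerate draw: fall back to a path
        g = nx.path_graph(max(n, 2))
    net = Network()
    rng = np.random.default_rng(seed)
    for u, v in sorted(g.edges()):
        w = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
        net.add_edge(f"n{u}", f"n{v}", w)
    return net


@pytest.fixture
def triangle():
    return build_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangles():
    return build_network(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def single_edge():
    return build_network([("a", "b")])


@pytest.fixture
def two_cliques_bridge_edge():
    """Two 4-cliques joined by a single inter-clique edge."""
    edges = []
    for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((block[i], block[j]))
    edges.append(("a1", "b1"))
    return build_network(edges)
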