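import networkx as nx
import pytest


def k6_minus_matching(prefix: str) -> nx.Graph:
    """K6 minus a perfect matching: 6 nodes, 12 edges, alpha=0.8, delta=0.8, R=2."""
    g = nx.complete_graph(6)
    g.remove_edges_from([(0, 1), (2, 3), (4, 5)])
    return nx.relabel_nodes(g, {i: f"{prefix}{i}" for i in range(6)})


@pytest.fixture
def bridged_blocks() -> tuple[nx.Graph, list[set]]:
    """Two dense 6-vertex blocks joined by a single bridge edge.

    Constructed so each block satisfies the default floors (alpha=0.8 >= 0.6,
    delta=0.8 >= 0.65, diameter 2) while the bridge endpoint has within-degree
    1 into the other block; the equilibrium partition is the two blocks with
    empty residual.
    """
    a = k6_minus_matching("a")
    b = k6_minus_matching("b")
    g = nx.union(a, b)
    g.add_edge("a0", "b0")
    return g, [set(a), set(b)]
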