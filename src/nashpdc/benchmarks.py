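"""Synthetic benchmark generators with known ground truth.

Three generators drive the validation experiments:

* Girvan-Newman planted 4-partition graphs (128 vertices in 4 modules of 32,
  expected total degree 16), where the mixing parameter ``mu`` is the
  expected fraction of a vertex's edges leaving its module;
* Erdos-Renyi G(n, p) null graphs, which carry no modular structure;
* edge-endpoint rewiring, perturbing a graph with probability ``rho`` per
  endpoint to study noise robustness.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class GNConfig:
    """Planted-partition benchmark parameters.

    The intra/inter edge probabilities follow from the expected degree and
    mixing parameter:

        p_in  = avg_degree * (1 - mu) / (module_size - 1)
        p_out = avg_degree * mu / (n_nodes - module_size)

    so each vertex has expected total degree ``avg_degree`` of which an
    expected fraction ``mu`` leaves its module.
    """

    n_nodes: int = 128
    n_modules: int = 4
    module_size: int = 32
    avg_degree: float = 16.0
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes != self.n_modules * self.module_size:
            raise ValueError(
                f"n_nodes ({self.n_nodes}) must equal n_modules * module_size "
                f"({self.n_modules} * {self.module_size})"
            )
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mixing parameter mu must lie in [0,1], got {self.mu}")

    @property
    def p_in(self) -> float:
        return self.avg_degree * (1.0 - self.mu) / (self.module_size - 1)

    @property
    def p_out(self) -> float:
        return self.avg_degree * self.mu / (self.n_nodes - self.module_size)


@dataclass
class LabeledNetwork:
    """A benchmark network together with its planted module partition."""

    network: nx.Graph
    truth: list[set]

    def __post_init__(self) -> None:
        universe = set()
        for cls in self.truth:
            if universe & cls:
                raise ValueError("truth classes must be disjoint")
            universe |= cls
        if universe != set(self.network):
            raise ValueError("truth classes must cover exactly the network's nodes")


def generate_gn(config: GNConfig) -> LabeledNetwork:
    """Generate one Girvan-Newman planted-partition instance.

    Every intra-module vertex pair is linked independently with probability
    ``p_in`` and every inter-module pair with ``p_out``.  Raises when the
    requested degree/mixing combination pushes either probability out of
    [0, 1].
    """
    for name, prob in (("p_in", config.p_in), ("p_out", config.p_out)):
        if not (0.0 <= prob <= 1.0):
            raise ValueError(
                f"infeasible GN configuration: {name} = {prob:.4f} outside [0, 1]"
            )
    g = nx.planted_partition_graph(
        config.n_modules,
        config.module_size,
        config.p_in,
        config.p_out,
        seed=config.seed,
    )
    truth = [set(block) for block in g.graph.pop("partition")]
    return LabeledNetwork(nx.Graph(g), truth)


def generate_er(n: int, edge_prob: float, seed: int = 0) -> nx.Graph:
    """Erdos-Renyi G(n, p) null network, seeded and reproducible."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError(f"edge probability must lie in [0,1], got {edge_prob}")
    return nx.gnp_random_graph(n, edge_prob, seed=seed)


def rewire(g: nx.Graph, rho: float, seed: int = 0) -> nx.Graph:
    """Rewire each edge endpoint to a uniformly random vertex with probability ``rho``.

    Each endpoint of each edge is considered independently.  Rewired edges
    that collide with an existing edge or form a self-loop are discarded, so
    the result remains a simple graph over the same vertex set; the input
    graph is never modified.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rewiring probability must lie in [0,1], got {rho}")
    rng = random.Random(seed)
    nodes = sorted(g.nodes, key=str)
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for u, v in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
        if rho > 0.0 and rng.random() < rho:
            u = rng.choice(nodes)
        if rho > 0.0 and rng.random() < rho:
            v = rng.choice(nodes)
        if u != v:
            out.add_edge(u, v)
    return out
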