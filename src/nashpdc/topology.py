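"""Graph-theoretic primitives that parameterize the dense-cover game.

For an induced subgraph G(S) on k = |S| vertices:

* degree density  alpha = (minimum within-S degree) / (k - 1)
* edge density    delta = |E(G(S))| / C(k, 2)
* R               the maximum pairwise shortest-path length (infinite when
                  G(S) is disconnected)

Singletons get alpha = delta = 0 and R = 0 by convention: they can never meet
positive density floors, matching their role as residual players rather than
covers.

The rule of order ranks players by the geometric mean of degree and local
transitivity; local transitivity t(v) is the fraction of neighbor pairs of v
that are themselves adjacent (0 when deg(v) < 2, where no triple is centered
on v).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx


@dataclass(frozen=True)
class SubgraphStats:
    """Cached statistics of one induced subgraph."""

    size: int
    min_within_degree: int
    edge_count: int
    degree_density: float
    edge_density: float
    diameter: float  # math.inf when the induced subgraph is disconnected

    def __post_init__(self) -> None:
        if not (0.0 <= self.degree_density <= 1.0):
            raise ValueError(f"degree density out of [0,1]: {self.degree_density}")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError(f"edge density out of [0,1]: {self.edge_density}")


def _require_node(g: nx.Graph, v: Hashable) -> None:
    if v not in g:
        raise ValueError(f"node {v!r} is not in the graph")


def p_neighborhood(g: nx.Graph, v: Hashable, p: int, closed: bool = False) -> set:
    """Vertices reachable from ``v`` by a path of length <= ``p``.

    The open neighborhood N_p(v) excludes ``v`` itself; the closed variant
    N_p[v] = N_p(v) | {v} includes it.
    """
    _require_node(g, v)
    if p < 1:
        raise ValueError(f"neighborhood order must be >= 1, got {p}")
    ball = set(nx.single_source_shortest_path_length(g, v, cutoff=p))
    if not closed:
        ball.discard(v)
    return ball


def subgraph_stats(g: nx.Graph, s: Iterable[Hashable]) -> SubgraphStats:
    """Compute size, within-degrees, densities and R for the subgraph induced by ``s``.

    Within-degrees ignore edges leaving ``s``.  R is the maximum pairwise
    shortest-path length inside the induced subgraph, ``math.inf`` when it is
    disconnected.
    """
    members = set(s)
    if not members:
        raise ValueError("cannot compute statistics of an empty vertex set")
    missing = [v for v in members if v not in g]
    if missing:
        raise ValueError(f"vertices not in graph: {missing!r}")
    k = len(members)
    if k == 1:
        return SubgraphStats(1, 0, 0, 0.0, 0.0, 0.0)
    adj = g.adj
    within_deg = {v: sum(1 for u in adj[v] if u in members) for v in members}
    m = sum(within_deg.values()) // 2
    alpha = min(within_deg.values()) / (k - 1)
    delta = m / (k * (k - 1) / 2)
    diameter = _diameter(adj, members)
    return SubgraphStats(k, min(within_deg.values()), m, alpha, delta, diameter)


def _diameter(adj, members: set) -> float:
    """Max pairwise shortest-path length within ``members``; inf if disconnected."""
    worst = 0
    for src in members:
        seen = {src}
        frontier = [src]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w in members and w not in seen:
                        seen.add(w)
                        nxt.append(w)
            frontier = nxt
        if len(seen) < len(members):
            return math.inf
        worst = max(worst, dist - 1)
    return float(worst)


def diameter_at_most(adj, members: set, p: int) -> bool:
    """True iff every pair in ``members`` is within distance ``p`` in the induced subgraph.

    Bounded BFS from every vertex, abandoning a source as soon as depth ``p``
    is exhausted, so the work per proposal stays proportional to the p-ball.
    """
    k = len(members)
    for src in members:
        seen = {src}
        frontier = [src]
        for _ in range(p):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w in members and w not in seen:
                        seen.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        if len(seen) < k:
            return False
    return True


def local_transitivity(g: nx.Graph, v: Hashable) -> float:
    """Triangles through ``v`` divided by the pairs of neighbors of ``v``.

    Returns 0.0 when deg(v) < 2 (no triple is centered on v).
    """
    _require_node(g, v)
    neighbors = list(g.adj[v])
    d = len(neighbors)
    if d < 2:
        return 0.0
    adj = g.adj
    triangles = 0
    for i in range(d):
        ni = adj[neighbors[i]]
        for j in range(i + 1, d):
            if neighbors[j] in ni:
                triangles += 1
    return triangles / (d * (d - 1) / 2)


def rank_players(g: nx.Graph) -> list:
    """The rule of order: nodes sorted by sqrt(deg * transitivity), descending.

    Ties break by degree descending, then node id ascending, so the order is
    a deterministic permutation of the vertex set.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank players of an empty graph")
    scores = {}
    for v in g:
        d = g.degree(v)
        scores[v] = math.sqrt(d * local_transitivity(g, v))
    return sorted(g.nodes, key=lambda v: (-scores[v], -g.degree(v), v))
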