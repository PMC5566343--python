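"""The partial dense vertex cover (PDC) game engine.

A partial dense vertex cover of an undirected graph G = (V, E) is a
collection of disjoint vertex subsets C_1 ... C_k, each inducing a subgraph
with degree density >= lambda, edge density >= gamma and diameter <= p, each
locally maximal, such that the residual graph over the uncovered vertices
contains no further subset with those properties.  Vertices are modeled as
selfish players; a Nash equilibrium of the sequential coalition-formation
game corresponds to a minimum partial dense vertex cover, and the engine
below (``nash_pdc``) plays one deterministic run of that game:

1. rank all players once by the geometric mean of degree and local
   transitivity (the rule of order);
2. the best-ranked active player proposes its closed p-th order neighborhood
   (within the residual game) as a coalition;
3. the proposal is refined by best-response dynamics -- members whose
   presence violates the density/diameter floors drop out weakest-first, and
   the surviving coalition absorbs any adjacent active player whose entry
   keeps it feasible (local maximality);
4. a stable coalition quits the game; a failed proposer never proposes
   again but may still join later coalitions.  Leftover players end as
   residual singletons.

``verify_cover_set`` checks an arbitrary cover against the definition,
property by property, and doubles as a brute-force test oracle through its
exhaustive residual search.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional

import networkx as nx

from .graph_io import ComplexSet
from .topology import (
    SubgraphStats,
    diameter_at_most,
    p_neighborhood,
    rank_players,
    subgraph_stats,
)

logger = logging.getLogger("nashpdc")


@dataclass(frozen=True)
class GameConfig:
    """All tunable symbols of the cover definition.

    lambda_   degree-density floor, in (0, 1]
    gamma     edge-density floor, in (0, 1]; lambda_ <= gamma
    p         diameter bound and neighborhood order, positive integer
    min_size  minimum coalition cardinality (>= 2); bare edges are excluded
              from being called complexes at the default of 3
    seed      recorded for any randomized tie-handling; the default engine
              is fully deterministic and never consumes it
    """

    lambda_: float = 0.6
    gamma: float = 0.65
    p: int = 2
    min_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ <= self.gamma <= 1.0):
            raise ValueError(
                f"need 0 < lambda <= gamma <= 1, got lambda={self.lambda_}, gamma={self.gamma}"
            )
        if self.p < 1:
            raise ValueError(f"diameter bound p must be >= 1, got {self.p}")
        if self.min_size < 2:
            raise ValueError(f"min_size must be >= 2, got {self.min_size}")


@dataclass(frozen=True)
class Coalition:
    """A stable coalition: members, the player that proposed it, cached stats."""

    members: frozenset
    proposer: Hashable
    stats: SubgraphStats

    def __post_init__(self) -> None:
        if self.proposer not in self.members:
            raise ValueError("proposer must belong to the coalition")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CoverSet:
    """Outcome of one game: disjoint coalitions plus residual singleton players."""

    coalitions: list[Coalition]
    residual: set
    config: GameConfig
    source_nodes: int

    def covered(self) -> set:
        out: set = set()
        for c in self.coalitions:
            out |= c.members
        return out

    def to_partition(self) -> list[set]:
        """Full partition of V: coalitions plus one singleton class per residual player."""
        classes = [set(c.members) for c in self.coalitions]
        classes.extend({v} for v in sorted(self.residual, key=str))
        return classes

    def to_complex_set(self, include_singletons: bool = False) -> ComplexSet:
        complexes = [set(c.members) for c in self.coalitions]
        if include_singletons:
            complexes.extend({v} for v in sorted(self.residual, key=str))
        return ComplexSet(complexes, name="nashpdc")


# ---------------------------------------------------------------------------
# coalition proposal and best-response refinement
# ---------------------------------------------------------------------------


def propose_coalition(
    g: nx.Graph, proposer: Hashable, config: GameConfig, active: Optional[set] = None
) -> set:
    """The proposer's opening move: its closed p-th order neighborhood.

    The ball is computed inside the residual game, i.e. paths may only pass
    through active (unassigned) players.
    """
    if active is None:
        active = set(g)
    if proposer not in active:
        raise ValueError(f"proposer {proposer!r} is not an active player")
    # bounded BFS confined to active players
    seen = {proposer}
    frontier = [proposer]
    adj = g.adj
    for _ in range(config.p):
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w in active and w not in seen:
                    seen.add(w)
                    nxt.append(w)
        if not nxt:
            break
        frontier = nxt
    return seen


def _feasible(adj, members: set, within_deg: dict, m: int, config: GameConfig) -> bool:
    """Definition feasibility for a candidate with cached within-degrees.

    Cheap density checks run before the bounded diameter BFS, so the
    expensive check only fires on candidates that are already dense.
    """
    k = len(members)
    if k < 2:
        return False
    if min(within_deg[v] for v in members) < config.lambda_ * (k - 1):
        return False
    if m < config.gamma * k * (k - 1) / 2:
        return False
    return diameter_at_most(adj, members, config.p)


def refine_coalition(
    g: nx.Graph,
    candidate: Iterable[Hashable],
    proposer: Hashable,
    config: GameConfig,
    active: Optional[set] = None,
) -> Optional[Coalition]:
    """Best-response refinement of a proposed coalition.

    Prune: while the density/diameter floors are violated and more than
    ``min_size`` members remain, the non-proposer member with the smallest
    within-coalition degree leaves (ties: higher id leaves first) -- dropping
    the weakest-connected member is the greedy step that most directly raises
    both density ratios.  Failure if the floors still cannot be met.

    Grow: the surviving coalition then absorbs, one at a time, the active
    outside vertex with the most links into it whose entry preserves all
    floors (ties: lower id first), until none remains.  This enforces local
    maximality.

    Returns the stable :class:`Coalition`, or ``None`` when no feasible
    coalition of size >= ``min_size`` survives around the proposer.
    """
    if active is None:
        active = set(g)
    members = set(candidate)
    if proposer not in members:
        raise ValueError("proposer must belong to the candidate set")
    if not members <= active:
        raise ValueError("candidate contains inactive players")

    adj = g.adj
    within_deg = {v: sum(1 for u in adj[v] if u in members) for v in members}
    m = sum(within_deg.values()) // 2

    # --- prune ---
    while (
        len(members) > config.min_size
        and not _feasible(adj, members, within_deg, m, config)
    ):
        victim = max(
            (v for v in members if v != proposer),
            key=lambda v: (-within_deg[v], v),
        )
        members.remove(victim)
        m -= within_deg.pop(victim)
        for u in adj[victim]:
            if u in members:
                within_deg[u] -= 1
    if len(members) < config.min_size or not _feasible(
        adj, members, within_deg, m, config
    ):
        return None

    # --- grow to local maximality ---
    while True:
        links: dict = {}
        for v in members:
            for u in adj[v]:
                if u in active and u not in members:
                    links[u] = links.get(u, 0) + 1
        added = False
        for u in sorted(links, key=lambda u: (-links[u], u)):
            trial = members | {u}
            trial_deg = dict(within_deg)
            trial_deg[u] = links[u]
            for w in adj[u]:
                if w in members:
                    trial_deg[w] += 1
            if _feasible(adj, trial, trial_deg, m + links[u], config):
                members = trial
                within_deg = trial_deg
                m += links[u]
                added = True
                break
        if not added:
            break

    return Coalition(frozenset(members), proposer, subgraph_stats(g, members))


# ---------------------------------------------------------------------------
# the sequential game
# ---------------------------------------------------------------------------


def nash_pdc(g: nx.Graph, config: GameConfig = GameConfig()) -> CoverSet:
    """Play the sequential PDC game to a Nash-stable partition.

    The rule of order is computed once on the full graph.  Proposers are
    taken in rank order among still-active players; a successful coalition's
    members quit the game, a failed proposer is marked exhausted (it cannot
    propose again but remains joinable).  The game ends when every active
    player has had its proposal, and the leftover players form the residual.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot play the game on an empty graph")
    order = rank_players(g)
    active = set(g)
    coalitions: list[Coalition] = []
    for proposer in order:
        if proposer not in active:
            continue  # already quit with a coalition
        candidate = propose_coalition(g, proposer, config, active)
        coalition = refine_coalition(g, candidate, proposer, config, active)
        if coalition is None:
            logger.debug("proposal by %r failed; player exhausted", proposer)
            continue
        logger.info(
            "coalition %d: %d members proposed by %r (alpha=%.3f delta=%.3f R=%g)",
            len(coalitions) + 1,
            len(coalition),
            proposer,
            coalition.stats.degree_density,
            coalition.stats.edge_density,
            coalition.stats.diameter,
        )
        coalitions.append(coalition)
        active -= coalition.members
    cover = CoverSet(coalitions, active, config, g.number_of_nodes())
    _assert_partition(g, cover)
    return cover


def _assert_partition(g: nx.Graph, cover: CoverSet) -> None:
    covered = cover.covered()
    total = sum(len(c.members) for c in cover.coalitions)
    if len(covered) != total:
        raise AssertionError("coalitions overlap")
    if covered | cover.residual != set(g) or covered & cover.residual:
        raise AssertionError("coalitions and residual do not partition V")


# ---------------------------------------------------------------------------
# definition verifier / test oracle
# ---------------------------------------------------------------------------


def _stats_feasible(stats: SubgraphStats, config: GameConfig) -> bool:
    return (
        stats.degree_density >= config.lambda_
        and stats.edge_density >= config.gamma
        and stats.diameter <= config.p
    )


def verify_cover_set(
    g: nx.Graph,
    cover: CoverSet,
    config: GameConfig,
    exhaustive_residual_check: bool = False,
    residual_bound: int = 15,
) -> tuple[bool, list[str]]:
    """Check a cover against the definition, one named violation per property.

    (a) coalitions are non-empty; (b) pairwise disjoint; (c) every member is
    a vertex of g; (d) induced diameter <= p; (e) degree density >= lambda
    and edge density >= gamma; (f) local maximality: no residual vertex can
    join any coalition while preserving (d)-(e); (g) -- only when
    ``exhaustive_residual_check`` is set and the residual has at most
    ``residual_bound`` vertices -- the residual induced graph contains no
    vertex subset of size >= min_size satisfying (d)-(e), verified by
    exhaustive subset enumeration.
    """
    violations: list[str] = []
    nodes = set(g)
    members_list = [set(c.members) for c in cover.coalitions]

    for i, mem in enumerate(members_list):
        if not mem:
            violations.append(f"a: coalition {i} is empty")
    for i, j in itertools.combinations(range(len(members_list)), 2):
        if members_list[i] & members_list[j]:
            violations.append(f"b: coalitions {i} and {j} overlap")
            break
    stray = (set().union(*members_list) if members_list else set()) - nodes
    if stray or cover.residual - nodes:
        violations.append(f"c: cover refers to vertices outside the graph: "
                          f"{sorted(stray | (cover.residual - nodes), key=str)!r}")

    for i, mem in enumerate(members_list):
        if not mem or not mem <= nodes:
            continue
        stats = subgraph_stats(g, mem)
        if stats.diameter > config.p:
            violations.append(f"d: coalition {i} has diameter {stats.diameter:g} > {config.p}")
        if stats.degree_density < config.lambda_:
            violations.append(
                f"e: coalition {i} degree density {stats.degree_density:.4f} < {config.lambda_}"
            )
        if stats.edge_density < config.gamma:
            violations.append(
                f"e: coalition {i} edge density {stats.edge_density:.4f} < {config.gamma}"
            )

    # (f) local maximality against residual vertices
    residual = set(cover.residual) & nodes
    for i, mem in enumerate(members_list):
        if not mem or not mem <= nodes:
            continue
        neighbors = {u for v in mem for u in g.adj[v] if u in residual}
        for u in sorted(neighbors, key=str):
            if _stats_feasible(subgraph_stats(g, mem | {u}), config):
                violations.append(
                    f"f: residual vertex {u!r} can join coalition {i} feasibly"
                )
                break

    if exhaustive_residual_check and len(residual) <= residual_bound:
        found = find_feasible_subset(g.subgraph(residual), config)
        if found is not None:
            violations.append(
                f"g: residual contains feasible subset {sorted(found, key=str)!r}"
            )

    return (not violations, violations)


def find_feasible_subset(g: nx.Graph, config: GameConfig) -> Optional[frozenset]:
    """Exhaustively search ``g`` for any vertex subset of size >= min_size
    meeting the diameter and density floors.  Brute-force oracle; intended
    for graphs of at most ~15 vertices."""
    nodes = sorted(g, key=str)
    for k in range(config.min_size, len(nodes) + 1):
        for combo in itertools.combinations(nodes, k):
            if _stats_feasible(subgraph_stats(g, combo), config):
                return frozenset(combo)
    return None
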