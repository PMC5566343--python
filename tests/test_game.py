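import itertools
import random

import networkx as nx
import pytest

from nashpdc import (
    Coalition,
    CoverSet,
    GameConfig,
    find_feasible_subset,
    nash_pdc,
    p_neighborhood,
    propose_coalition,
    refine_coalition,
    subgraph_stats,
    verify_cover_set,
)
from nashpdc.cli import child_seeds


class TestGameConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_": 0.0},
            {"lambda_": 0.7, "gamma": 0.6},  # lambda > gamma
            {"gamma": 1.1},
            {"p": 0},
            {"min_size": 1},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            GameConfig(**kwargs)

    def test_defaults(self):
        cfg = GameConfig()
        assert (cfg.lambda_, cfg.gamma, cfg.p, cfg.min_size) == (0.6, 0.65, 2, 3)


class TestProposeCoalition:
    def test_clique_proposal_covers_clique(self):
        g = nx.complete_graph(6)
        assert propose_coalition(g, 0, GameConfig()) == set(range(6))

    def test_isolated_proposer(self):
        g = nx.Graph()
        g.add_node("x")
        assert propose_coalition(g, "x", GameConfig()) == {"x"}

    def test_inactive_proposer_raises(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError):
            propose_coalition(g, 0, GameConfig(), active={1, 2, 3})

    def test_ball_confined_to_active_players(self):
        # path 0-1-2: with 1 inactive, 2 is unreachable from 0
        g = nx.path_graph(3)
        assert propose_coalition(g, 0, GameConfig(), active={0, 2}) == {0}

    def test_proposal_within_closed_ball(self):
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.15, seed=seed)
            cfg = GameConfig()
            for v in list(g)[:10]:
                ball = p_neighborhood(g, v, cfg.p, closed=True)
                assert propose_coalition(g, v, cfg) <= ball


class TestRefineCoalition:
    def test_clique_needs_no_refinement(self):
        g = nx.complete_graph(6)
        c = refine_coalition(g, set(range(6)), 0, GameConfig())
        assert set(c.members) == set(range(6))
        assert c.stats.degree_density == 1.0 and c.stats.diameter == 1.0

    def test_bridge_vertex_pruned_first(self, bridged_blocks):
        g, (block_a, block_b) = bridged_blocks
        candidate = block_a | {"b0"}
        c = refine_coalition(g, candidate, "a2", GameConfig())
        assert set(c.members) == block_a
        ok, violations = verify_cover_set(
            g, CoverSet([c], set(g) - block_a, GameConfig(), g.number_of_nodes()),
            GameConfig(),
        )
        # block_b stays intact in the residual, so only local maximality of the
        # reported coalition is relevant here; property (e) and (d) must hold
        assert not any(v.startswith(("d", "e")) for v in violations)

    def test_sparse_star_fails(self):
        g = nx.star_graph(4)  # center 0 + 4 leaves
        cfg = GameConfig()
        assert refine_coalition(g, set(g), 0, cfg) is None
        # brute-force: no subset of size >= 3 containing the center is feasible
        for k in range(3, 6):
            for combo in itertools.combinations(range(5), k):
                if 0 in combo:
                    s = subgraph_stats(g, combo)
                    assert s.edge_density < cfg.gamma or s.degree_density < cfg.lambda_

    def test_growth_restores_local_maximality(self):
        # prune-free candidate that is a strict subset of a clique: growth
        # must absorb the remaining clique members
        g = nx.complete_graph(6)
        c = refine_coalition(g, {0, 1, 2}, 0, GameConfig())
        assert set(c.members) == set(range(6))

    def test_proposer_never_pruned(self):
        # proposer is the weakest member; pruning must sacrifice others
        g = nx.complete_graph(5)
        g.add_edge(0, "w")  # 'w' hangs off the clique
        c = refine_coalition(g, {0, 1, 2, 3, 4, "w"}, "w", GameConfig())
        assert c is None or "w" in c.members


class TestNashPDC:
    def test_bridged_blocks_equilibrium(self, bridged_blocks):
        g, blocks = bridged_blocks
        cover = nash_pdc(g, GameConfig())
        assert sorted(map(sorted, (c.members for c in cover.coalitions))) == sorted(
            map(sorted, blocks)
        )
        assert cover.residual == set()

    def test_single_clique(self):
        g = nx.complete_graph(5)
        cover = nash_pdc(g, GameConfig())
        assert len(cover.coalitions) == 1
        assert set(cover.coalitions[0].members) == set(range(5))
        assert cover.residual == set()

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            nash_pdc(nx.Graph(), GameConfig())

    def test_partition_property(self):
        for seed in range(10):
            g = nx.gnp_random_graph(25, 0.3, seed=seed)
            cover = nash_pdc(g, GameConfig())
            covered = cover.covered()
            assert covered | cover.residual == set(g)
            assert not covered & cover.residual
            assert sum(len(c.members) for c in cover.coalitions) == len(covered)

    def test_soundness_of_emitted_coalitions(self):
        cfg = GameConfig()
        for seed in range(10):
            g = nx.gnp_random_graph(25, 0.3, seed=seed)
            for c in nash_pdc(g, cfg).coalitions:
                assert len(c.members) >= cfg.min_size
                s = subgraph_stats(g, c.members)
                assert s.degree_density >= cfg.lambda_
                assert s.edge_density >= cfg.gamma
                assert s.diameter <= cfg.p

    def test_determinism(self):
        g = nx.gnp_random_graph(40, 0.25, seed=5)
        a = nash_pdc(g, GameConfig())
        b = nash_pdc(g, GameConfig())
        assert [c.members for c in a.coalitions] == [c.members for c in b.coalitions]
        assert [c.proposer for c in a.coalitions] == [c.proposer for c in b.coalitions]
        assert a.residual == b.residual

    def test_tightening_gamma_keeps_coalitions_feasible_at_looser_gamma(self):
        g = nx.gnp_random_graph(30, 0.4, seed=3)
        loose = GameConfig(gamma=0.65)
        tight = GameConfig(gamma=0.8)
        for c in nash_pdc(g, tight).coalitions:
            s = subgraph_stats(g, c.members)
            assert s.edge_density >= tight.gamma >= loose.gamma

    def test_small_scale_oracle_equivalence(self):
        """Emitted coalitions are locally maximal feasible sets and the
        residual holds no feasible set, per exhaustive subset enumeration."""
        cfg = GameConfig()
        for s in child_seeds(99, 40):
            rng = random.Random(s)
            g = nx.gnp_random_graph(rng.randint(4, 12), rng.uniform(0.2, 0.8), seed=s)
            cover = nash_pdc(g, cfg)
            ok, violations = verify_cover_set(
                g, cover, cfg, exhaustive_residual_check=True
            )
            assert ok, violations


class TestVerifyCoverSet:
    def _cover(self, g, members_list, cfg):
        coalitions = [
            Coalition(frozenset(m), next(iter(m)), subgraph_stats(g, m))
            for m in members_list
        ]
        covered = set().union(*members_list) if members_list else set()
        return CoverSet(coalitions, set(g) - covered, cfg, g.number_of_nodes())

    def test_engine_output_passes(self, bridged_blocks):
        g, _ = bridged_blocks
        cfg = GameConfig()
        ok, violations = nash_pdc(g, cfg), None
        ok, violations = verify_cover_set(g, nash_pdc(g, cfg), cfg, True)
        assert ok, violations

    def test_overlap_violates_disjointness(self):
        g = nx.complete_graph(6)
        cfg = GameConfig()
        ok, violations = verify_cover_set(
            g, self._cover(g, [{0, 1, 2, 3}, {3, 4, 5}], cfg), cfg
        )
        assert not ok
        assert any(v.startswith("b") for v in violations)

    def test_feasible_residual_block_violates_exhaustiveness(self, bridged_blocks):
        g, (block_a, block_b) = bridged_blocks
        cfg = GameConfig()
        cover = self._cover(g, [block_a], cfg)
        ok, violations = verify_cover_set(g, cover, cfg, exhaustive_residual_check=True)
        assert not ok
        assert any(v.startswith("g") for v in violations)
        # without the exhaustive flag the same cover raises no (g) violation
        ok2, violations2 = verify_cover_set(g, cover, cfg)
        assert not any(v.startswith("g") for v in violations2)

    def test_sparse_coalition_violates_density(self):
        g = nx.path_graph(6)
        cfg = GameConfig()
        ok, violations = verify_cover_set(g, self._cover(g, [{0, 1, 2, 3}], cfg), cfg)
        assert not ok
        assert any(v.startswith("e") for v in violations)

    def test_joinable_neighbor_violates_local_maximality(self):
        g = nx.complete_graph(5)
        cfg = GameConfig()
        ok, violations = verify_cover_set(g, self._cover(g, [{0, 1, 2, 3}], cfg), cfg)
        assert not ok
        assert any(v.startswith("f") for v in violations)

    def test_find_feasible_subset_oracle(self, bridged_blocks):
        g, (block_a, _) = bridged_blocks
        cfg = GameConfig()
        found = find_feasible_subset(g.subgraph(block_a), cfg)
        assert found is not None
        assert find_feasible_subset(nx.path_graph(5), cfg) is None
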