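"""Path mining: Dijkstra correctness, deterministic tie-breaks, betweenness."""

import numpy as np
import pytest

from pathprio.network import ConfidenceEdge, build_network
from pathprio.paths import (
    all_pairs_seed_paths,
    betweenness_counts,
    collapse_to_genes,
    dijkstra_path,
    _mine_interior_counts,
)

from .conftest import brute_force_cost, random_weighted_network


class TestDijkstraPath:
    def test_source_equals_target(self, triangle_network):
        p = dijkstra_path(triangle_network, "A", "A")
        assert p.nodes == ("A",) and p.cost == 0

    def test_two_hop_beats_expensive_direct(self, triangle_network):
        p = dijkstra_path(triangle_network, "A", "C")
        assert p.nodes == ("A", "B", "C") and p.cost == 2

    def test_unknown_node_raises(self, triangle_network):
        with pytest.raises(KeyError):
            dijkstra_path(triangle_network, "A", "Z")

    def test_unreachable_returns_none(self):
        net = build_network([
            ConfidenceEdge("A", "B", 500), ConfidenceEdge("C", "D", 500)
        ])
        assert dijkstra_path(net, "A", "C") is None

    def test_lexicographic_tie_break(self):
        # two equal-cost routes S-A-T and S-B-T: the A route must win
        net = build_network([
            ConfidenceEdge("S", "A", 900), ConfidenceEdge("A", "T", 900),
            ConfidenceEdge("S", "B", 900), ConfidenceEdge("B", "T", 900),
        ])
        assert dijkstra_path(net, "S", "T").nodes == ("S", "A", "T")

    def test_cost_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            net = random_weighted_network(rng)
            nodes = sorted(net.nodes)
            s, t = nodes[0], nodes[-1]
            p = dijkstra_path(net, s, t)
            assert p is not None
            oracle = brute_force_cost(net, s, t)
            assert p.cost == pytest.approx(oracle)
            # returned sequence is a real path with consistent cost
            g = net.graph
            assert sum(g[u][v]["cost"] for u, v in zip(p.nodes, p.nodes[1:])) == \
                pytest.approx(p.cost)
            assert len(set(p.nodes)) == len(p.nodes)

    def test_adding_an_edge_never_increases_cost(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_weighted_network(rng)
            nodes = sorted(net.nodes)
            s, t = nodes[0], nodes[-1]
            before = dijkstra_path(net, s, t).cost
            pairs = [
                (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                if not net.graph.has_edge(a, b)
            ]
            if not pairs:
                continue
            a, b = pairs[int(rng.integers(len(pairs)))]
            net.set_edge_score(a, b, int(rng.integers(1, 1000)))
            assert dijkstra_path(net, s, t).cost <= before


class TestAllPairsSeedPaths:
    def test_needs_two_seeds(self, triangle_network):
        with pytest.raises(ValueError):
            all_pairs_seed_paths(triangle_network, {"A"})

    def test_pair_accounting_with_isolated_seed(self):
        net = build_network([
            ConfidenceEdge("A", "B", 500), ConfidenceEdge("C", "D", 500)
        ])
        ps = all_pairs_seed_paths(net, {"A", "B", "C"})
        assert len(ps.paths) == 1
        assert sorted(ps.skipped_pairs) == [("A", "C"), ("B", "C")]
        assert ps.n_pairs == 3

    def test_adjacent_seeds_have_no_interior(self):
        net = build_network([ConfidenceEdge("A", "B", 999)])
        ps = all_pairs_seed_paths(net, {"A", "B"})
        assert ps.paths[0].nodes == ("A", "B")

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(5)
        net = random_weighted_network(rng, n_max=8)
        seeds = sorted(net.nodes)[:3]
        a = all_pairs_seed_paths(net, seeds)
        b = all_pairs_seed_paths(net, seeds)
        assert [p.nodes for p in a.paths] == [p.nodes for p in b.paths]
        assert [p.cost for p in a.paths] == [p.cost for p in b.paths]

    def test_fifty_nine_seeds_give_1711_paths(self):
        # complete graph over 59 proteins: every pair connected
        proteins = [f"E{i:03d}" for i in range(59)]
        hub_edges = [ConfidenceEdge("HUB", p, 999) for p in proteins]
        ps = all_pairs_seed_paths(build_network(hub_edges), proteins)
        assert len(ps.paths) == 59 * 58 // 2 == 1711


class TestBetweennessCounts:
    def test_single_interior_node(self, triangle_network):
        ps = all_pairs_seed_paths(triangle_network, {"A", "C"})
        table = betweenness_counts(ps, {"A", "C"})
        assert table.counts == {"B": 1}

    def test_hand_counted_three_paths(self):
        # unique optima by construction: A-X-B (cost 3), A-X-C (cost 4),
        # B-Y-C (cost 2); all alternatives strictly costlier
        net = build_network([
            ConfidenceEdge("A", "X", 999), ConfidenceEdge("X", "B", 998),
            ConfidenceEdge("X", "C", 997), ConfidenceEdge("B", "Y", 999),
            ConfidenceEdge("Y", "C", 999),
        ])
        ps = all_pairs_seed_paths(net, {"A", "B", "C"})
        assert {p.nodes for p in ps.paths} == {
            ("A", "X", "B"), ("A", "X", "C"), ("B", "Y", "C")}
        table = betweenness_counts(ps, {"A", "B", "C"})
        assert table.counts == {"X": 2, "Y": 1}

    def test_star_hub_counts_all_pairs(self, star_network):
        seeds = ["L1", "L2", "L3", "L4"]
        ps = all_pairs_seed_paths(star_network, seeds)
        table = betweenness_counts(ps, seeds)
        assert table.counts == {"H": 6}  # C(4,2)

    def test_seed_exclusion_flag(self):
        # seed B lies on the A-C path interior
        net = build_network([
            ConfidenceEdge("A", "B", 999), ConfidenceEdge("B", "C", 999),
            ConfidenceEdge("A", "C", 100),
        ])
        ps = all_pairs_seed_paths(net, {"A", "B", "C"})
        assert betweenness_counts(ps, {"A", "B", "C"}).counts == {}
        incl = betweenness_counts(ps, {"A", "B", "C"}, include_seeds=True)
        assert incl.counts == {"B": 1}

    def test_conservation_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            net = random_weighted_network(rng)
            nodes = sorted(net.nodes)
            if len(nodes) < 3:
                continue
            seeds = nodes[: max(2, len(nodes) // 2)]
            ps = all_pairs_seed_paths(net, seeds)
            interior_total = sum(len(p.nodes) - 2 for p in ps.paths)
            with_seeds = betweenness_counts(ps, seeds, include_seeds=True)
            assert sum(with_seeds.counts.values()) == interior_total
            without = betweenness_counts(ps, seeds)
            seed_interior = sum(
                1 for p in ps.paths for n in p.interior if n in set(seeds))
            assert sum(without.counts.values()) == interior_total - seed_interior
            assert all(c <= len(ps.paths) for c in without.counts.values())

    def test_count_kernel_matches_path_objects(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            net = random_weighted_network(rng)
            comp = net.compiled()
            nodes = sorted(net.nodes)
            seeds = nodes[: max(2, len(nodes) - 2)]
            sidx = np.array([comp.index[s] for s in seeds])
            fast = _mine_interior_counts(comp, sidx)
            slow = _mine_interior_counts(comp, sidx, force_python=True)
            assert (fast == slow).all()
            ps = all_pairs_seed_paths(net, seeds)
            ref = betweenness_counts(ps, seeds, include_seeds=True)
            from_kernel = {
                comp.labels[i]: int(c) for i, c in enumerate(fast) if c > 0
            }
            assert from_kernel == ref.counts


def test_collapse_to_genes_takes_max():
    from pathprio.paths import BetweennessTable

    table = BetweennessTable({"P1": 5, "P2": 3, "P3": 1})
    collapsed = collapse_to_genes(table, {"P1": ["G1"], "P2": ["G1"], "P3": ["G2"]})
    assert collapsed.counts == {"G1": 5, "G2": 1}
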