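"""Synthetic-data generators: determinism, topology, planted structure."""

import numpy as np
import pytest

from pathprio.paths import all_pairs_seed_paths, betweenness_counts
from pathprio.simulate import (
    generate_annotation,
    generate_network,
    generate_reference_list,
    generate_scenario,
    plant_connectors,
)


class TestGenerateNetwork:
    def test_single_attachment_yields_tree(self):
        net = generate_network(10, 1, rng_seed=1)
        assert len(net) == 10 and net.n_edges == 9

    def test_deterministic_under_seed(self):
        a = generate_network(500, 3, rng_seed=7)
        b = generate_network(500, 3, rng_seed=7)
        assert sorted(a.graph.edges(data="score")) == sorted(b.graph.edges(data="score"))

    def test_heavy_tailed_degrees(self):
        for seed in range(20):
            net = generate_network(500, 3, rng_seed=seed)
            degs = np.array([d for _, d in net.graph.degree()])
            assert degs.max() >= 3 * np.median(degs)

    def test_scores_within_string_practical_range(self):
        net = generate_network(200, 2, rng_seed=3)
        scores = [d["score"] for _, _, d in net.graph.edges(data=True)]
        assert min(scores) >= 150 and max(scores) <= 999

    def test_erdos_renyi_alternative_is_connected(self):
        import networkx as nx

        net = generate_network(200, 3, rng_seed=5, topology="erdos_renyi")
        assert nx.is_connected(net.graph)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_network(5, 1)
        with pytest.raises(ValueError):
            generate_network(100, 0)


class TestPlantConnectors:
    def test_full_attachment_connector_dominates_pairs(self):
        # seeds pairwise non-adjacent, one connector wired to every seed:
        # its count is exactly C(n_seeds, 2) when no competing cost-2 route
        # exists, which the exhaustive small case verifies
        net = generate_network(30, 1, rng_seed=13)  # tree: no cheap triangles
        scen = plant_connectors(net, n_seeds=6, n_connectors=1,
                                attach_fraction=1.0, rng_seed=2)
        conn = next(iter(scen.true_connectors))
        ps = all_pairs_seed_paths(scen.network, scen.seed_proteins)
        counts = betweenness_counts(ps, scen.seed_proteins)
        assert counts[conn] == 15  # C(6,2)

    def test_null_scenario_has_empty_truth(self):
        net = generate_network(50, 2, rng_seed=1)
        scen = plant_connectors(net, n_seeds=5, n_connectors=0, rng_seed=1)
        assert scen.true_connectors == frozenset()

    def test_determinism_and_disjointness(self):
        net = generate_network(100, 2, rng_seed=4)
        a = plant_connectors(net, 10, 2, 0.5, rng_seed=9)
        b = plant_connectors(net, 10, 2, 0.5, rng_seed=9)
        assert a.seed_proteins == b.seed_proteins
        assert a.true_connectors == b.true_connectors
        assert sorted(a.network.graph.edges(data="score")) == \
            sorted(b.network.graph.edges(data="score"))
        assert not (set(a.seed_proteins) & a.true_connectors)

    def test_every_seed_covered_when_budget_allows(self):
        net = generate_network(100, 2, rng_seed=4)
        scen = plant_connectors(net, 10, 3, 0.5, rng_seed=9)
        g = scen.network.graph
        for s in scen.seed_proteins:
            assert any(g.has_edge(s, c) and g[s][c]["score"] == 999
                       for c in scen.true_connectors)

    def test_infeasible_sizes_rejected(self):
        net = generate_network(20, 1, rng_seed=0)
        with pytest.raises(ValueError):
            plant_connectors(net, 15, 10, 0.5)
        with pytest.raises(ValueError):
            plant_connectors(net, 5, 1, 0.0)

    def test_scenario_satisfies_pipeline_preconditions(self):
        scen = generate_scenario(rng_seed=3)
        assert len(scen.seeds) >= 2
        assert all(p in scen.network for p in scen.seed_proteins)
        assert all(g in scen.gene_map for g in scen.seeds)
        assert not (set(scen.seed_proteins) & scen.true_connectors)


class TestGenerateAnnotation:
    def test_empty_annotation(self):
        ann = generate_annotation(["A", "B"], n_terms=5, terms_per_gene=0)
        assert len(ann.background) == 0

    def test_deterministic(self):
        genes = [f"G{i}" for i in range(30)]
        a = generate_annotation(genes, rng_seed=5)
        b = generate_annotation(genes, rng_seed=5)
        assert a.terms() == b.terms()
        assert all(a.genes_for_term(t) == b.genes_for_term(t) for t in a.terms())

    def test_planted_block_is_enriched(self):
        from pathprio.enrichment import term_enrichment_pvalue

        hits = 0
        n_seeds_tested = 20
        for seed in range(n_seeds_tested):
            genes = [f"G{i:03d}" for i in range(200)]
            target = genes[:10]
            ann = generate_annotation(
                genes, n_terms=30, terms_per_gene=3,
                enriched_sets=[target], rng_seed=seed)
            block_terms = [t for t in ann.terms() if t >= "T0030"]
            ok = True
            for t in block_terms:
                members = ann.genes_for_term(t)
                k = len(members & set(target))
                p = term_enrichment_pvalue(
                    len(set(target) & ann.background), k,
                    len(members), len(ann.background))
                ok &= p < 0.01
            hits += ok
        assert hits >= 0.95 * n_seeds_tested


class TestGenerateReferenceList:
    def test_exact_size_and_overlap(self):
        universe = [f"G{i:04d}" for i in range(3000)]
        target = universe[:25]
        ref = generate_reference_list(universe, 742, target, 6, rng_seed=1)
        assert len(ref) == 742
        assert len(set(ref) & set(target)) == 6

    def test_disjoint_and_contained_extremes(self):
        universe = [f"G{i}" for i in range(100)]
        target = universe[:10]
        assert not set(generate_reference_list(universe, 20, target, 0, 1)) & set(target)
        full = generate_reference_list(universe, 10, target, 10, 1)
        assert set(full) == set(target)

    def test_infeasible_counts_rejected(self):
        universe = [f"G{i}" for i in range(50)]
        with pytest.raises(ValueError):
            generate_reference_list(universe, 10, universe[:3], 5, 1)
        with pytest.raises(ValueError):
            generate_reference_list(universe, 49, universe[:40], 0, 1)


def test_scenario_round_trips_through_files(tmp_path):
    from pathprio.model import ShortestPathGeneModel

    scen = generate_scenario(n_nodes=60, n_seeds=6, n_connectors=2, rng_seed=5)
    scen.write(tmp_path)
    model = ShortestPathGeneModel.from_files(
        str(tmp_path / "edges.tsv"), str(tmp_path / "seeds.txt"),
        str(tmp_path / "gene_map.tsv"))
    assert model.seed_proteins == scen.seed_proteins
    assert set(model.network.nodes) == scen.network.nodes
    # planted scores survive the round trip
    g1, g2 = scen.network.graph, model.network.graph
    assert all(g2[a][b]["score"] == d["score"] for a, b, d in g1.edges(data=True))
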