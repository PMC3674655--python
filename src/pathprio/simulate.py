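"""Synthetic study inputs: weighted networks with planted connector structure,
gene maps, annotations and reference lists.

The generator emulates the inputs of a STRING-based shortest-path study so
every pipeline stage is testable without downloads:

* background topology is preferential attachment (PPI degree distributions
  are heavy-tailed); an Erdos-Renyi alternative is available for null
  calibration work;
* edge confidences are drawn over [150, 999] — STRING's practical range
  above its common 150 score floor — uniformly by default;
* "connectors" are non-seed nodes wired to a fraction of the seeds at
  maximal confidence (score 999, cost 1), which places them on many
  seed-pair minimum-cost paths: the planted ground truth the permutation
  stage should recover;
* annotations plant a dedicated block of terms on designated gene sets so
  profile similarity has a detectable signal;
* the reference list has an exactly controlled overlap with any given set.

Every generator is a pure function of its parameters and rng seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import yaml

from .network import GeneProteinMap, PPINetwork, build_network, ConfidenceEdge
from .profiles import GOAnnotation

__all__ = [
    "SyntheticScenario",
    "generate_network",
    "plant_connectors",
    "generate_annotation",
    "generate_reference_list",
    "generate_scenario",
]

SCORE_LO, SCORE_HI = 150, 999


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _protein_label(i: int) -> str:
    return f"P{i:05d}"


def _gene_label(i: int) -> str:
    return f"G{i:05d}"


def generate_network(
    n_nodes: int,
    edges_per_node: int = 3,
    score_distribution: str | Callable[[np.random.Generator, int], np.ndarray] = "uniform",
    rng_seed: int = 0,
    topology: str = "preferential_attachment",
) -> PPINetwork:
    """Connected random network with integer confidence scores on edges.

    topology="preferential_attachment" (default) grows a Barabasi-Albert
    graph with ``edges_per_node`` attachments per new node (a tree when 1);
    topology="erdos_renyi" draws a G(n, p) with matched expected edge count
    and keeps its largest connected component.

    score_distribution: "uniform" draws scores from Uniform{150..999}; a
    callable receives (rng, n_edges) and must return integer scores in
    [150, 999].
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if edges_per_node < 1:
        raise ValueError("edges_per_node must be >= 1")
    rng = _rng(rng_seed)
    if topology == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_nodes, edges_per_node,
                                     seed=int(rng.integers(2**31)))
    elif topology == "erdos_renyi":
        p = min(1.0, 2 * edges_per_node / max(1, n_nodes - 1))
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant).copy()
    else:
        raise ValueError(f"unknown topology {topology!r}")

    n_edges = g.number_of_edges()
    if callable(score_distribution):
        scores = np.asarray(score_distribution(rng, n_edges), dtype=int)
        if scores.min() < SCORE_LO or scores.max() > SCORE_HI:
            raise ValueError("score distribution produced scores outside [150, 999]")
    elif score_distribution == "uniform":
        scores = rng.integers(SCORE_LO, SCORE_HI + 1, size=n_edges)
    else:
        raise ValueError(f"unknown score distribution {score_distribution!r}")

    edges = [
        ConfidenceEdge(_protein_label(a), _protein_label(b), int(s))
        for (a, b), s in zip(sorted(tuple(sorted(e)) for e in g.edges()), scores)
    ]
    return build_network(edges)


@dataclass
class SyntheticScenario:
    """A complete synthetic study: network, mapping, seeds and ground truth."""

    network: PPINetwork
    gene_map: GeneProteinMap
    seeds: list[str]                      # gene symbols
    seed_proteins: list[str]
    true_connectors: frozenset[str]       # protein ids, disjoint from seeds
    generator_params: dict = field(default_factory=dict)
    cancer_reference: list[str] | None = None
    annotation: GOAnnotation | None = None

    def write(self, outdir: str | Path) -> None:
        """Write every input file dialect the pipeline reads, plus a
        parameters manifest."""
        from .network import write_network

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "edges.tsv", "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for a, b, d in sorted(self.network.graph.edges(data=True)):
                a, b = (a, b) if a < b else (b, a)
                fh.write(f"{a}\t{b}\t{d['score']}\n")
        with open(out / "network.tsv", "w") as fh:
            write_network(self.network, fh)
        with open(out / "gene_map.tsv", "w") as fh:
            self.gene_map.write(fh)
        (out / "seeds.txt").write_text("\n".join(self.seeds) + "\n")
        (out / "true_connectors.txt").write_text(
            "\n".join(sorted(self.true_connectors)) + "\n")
        if self.cancer_reference is not None:
            (out / "reference.txt").write_text("\n".join(self.cancer_reference) + "\n")
        if self.annotation is not None:
            with open(out / "annotation.tsv", "w") as fh:
                self.annotation.write(fh)
        (out / "manifest.yaml").write_text(
            yaml.safe_dump(self.generator_params, sort_keys=True))


def _default_gene_map(proteins: Iterable[str], multi_map: dict[str, Sequence[str]] | None = None,
                      ) -> GeneProteinMap:
    gm = GeneProteinMap()
    for p in sorted(proteins):
        gm.add("G_" + p, p)
    if multi_map:
        for gene, prots in multi_map.items():
            gm.add(gene, prots)
    return gm


def plant_connectors(
    network: PPINetwork,
    n_seeds: int = 20,
    n_connectors: int = 3,
    attach_fraction: float = 0.5,
    rng_seed: int = 0,
    hub_exclusion_quantile: float = 0.2,
) -> SyntheticScenario:
    """Plant connector nodes wired to many seeds at maximal confidence.

    Selects disjoint seed and connector node sets at random from the nodes
    at or below the ``hub_exclusion_quantile`` of the degree distribution,
    then wires every connector to ceil(attach_fraction * n_seeds) distinct
    seeds with score 999 (cost 1). A connector adjacent to two seeds gives
    that pair a cost-2 route, usually the minimum, so connectors accumulate
    large path-occurrence counts. Gene symbols are "G_" + protein id.

    Two choices keep the planted ground truth identifiable:

    * seeds and connectors are drawn from the low-degree periphery (the
      bottom fifth of the degree distribution by default, which in a
      preferential-attachment graph is the minimum-degree shell). Disease
      genes are predominantly non-hub, and the choice keeps the ground truth
      identifiable: a well-connected planted node carries heavy shortest-path
      traffic for *any* seed set, so the permutation null is true for it and
      there is no seed-specific signal to recover;
    * when the total spoke budget allows it, attachments are dealt so that
      every seed receives at least one connector spoke before the remaining
      spokes are assigned at random. An uncovered seed reaches the rest of
      the seed set through whatever background node happens to be its
      cheapest gateway, which makes that gateway, not a connector, the
      seed-specific intermediate.
    """
    if not (0.0 < attach_fraction <= 1.0):
        raise ValueError("attach_fraction must lie in (0, 1]")
    nodes = sorted(network.nodes)
    if n_seeds + n_connectors > len(nodes):
        raise ValueError("n_seeds + n_connectors exceeds node count")
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds")
    rng = _rng(rng_seed)
    degrees = dict(network.graph.degree())
    cutoff = float(np.quantile([degrees[n] for n in nodes], hub_exclusion_quantile))
    pool = [n for n in nodes if degrees[n] <= cutoff]
    if n_seeds + n_connectors > len(pool):
        pool = nodes  # degenerate degree distribution: fall back to all nodes
    picked = rng.choice(len(pool), size=n_seeds + n_connectors, replace=False)
    seed_proteins = sorted(pool[i] for i in picked[:n_seeds])
    connectors = sorted(pool[i] for i in picked[n_seeds:])

    net = network.copy()
    n_attach = math.ceil(attach_fraction * n_seeds)
    attach: dict[str, set[int]] = {c: set() for c in connectors}
    if connectors and n_attach * n_connectors >= n_seeds:
        for t, si in enumerate(rng.permutation(n_seeds)):
            attach[connectors[t % n_connectors]].add(int(si))
    for conn in connectors:
        rest = [i for i in range(n_seeds) if i not in attach[conn]]
        need = n_attach - len(attach[conn])
        if need > 0:
            attach[conn].update(
                rest[i] for i in rng.choice(len(rest), size=need, replace=False))
        elif need < 0:  # coverage round over-filled this connector
            drop = rng.choice(sorted(attach[conn]), size=-need, replace=False)
            attach[conn].difference_update(int(d) for d in drop)
        for i in sorted(attach[conn]):
            net.set_edge_score(conn, seed_proteins[i], 999)

    gm = _default_gene_map(net.nodes)
    params = {
        "n_nodes": len(nodes),
        "n_seeds": n_seeds,
        "n_connectors": n_connectors,
        "attach_fraction": attach_fraction,
        "hub_exclusion_quantile": hub_exclusion_quantile,
        "rng_seed": int(rng_seed),
    }
    return SyntheticScenario(
        network=net,
        gene_map=gm,
        seeds=["G_" + p for p in seed_proteins],
        seed_proteins=seed_proteins,
        true_connectors=frozenset(connectors),
        generator_params=params,
    )


def generate_annotation(
    genes: Sequence[str],
    n_terms: int = 50,
    terms_per_gene: int = 3,
    enriched_sets: Sequence[Iterable[str]] = (),
    rng_seed: int = 0,
    block_size: int = 5,
    block_prob: float = 0.9,
) -> GOAnnotation:
    """Random gene-term annotation with planted enrichment blocks.

    Each gene receives ``terms_per_gene`` random background terms. For every
    designated enriched set, a dedicated block of ``block_size`` fresh terms
    is assigned to its members with probability ``block_prob`` each, so the
    block terms come out strongly enriched in that set.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _rng(rng_seed)
    ann = GOAnnotation()
    terms = [f"T{i:04d}" for i in range(n_terms)]
    for gene in genes:
        if terms_per_gene > 0:
            for t in rng.choice(n_terms, size=min(terms_per_gene, n_terms), replace=False):
                ann.annotate(gene, terms[t])
    next_term = n_terms
    for s in enriched_sets:
        block = [f"T{i:04d}" for i in range(next_term, next_term + block_size)]
        next_term += block_size
        for gene in sorted(set(s)):
            for bt in block:
                if rng.random() < block_prob:
                    ann.annotate(gene, bt)
    return ann


def generate_reference_list(
    universe: Sequence[str],
    size: int,
    overlap_with: Iterable[str] = (),
    n_overlap: int = 0,
    rng_seed: int = 0,
) -> list[str]:
    """Reference gene list of exactly ``size`` members, exactly ``n_overlap``
    of which fall inside ``overlap_with``."""
    target = sorted(set(overlap_with) & set(universe))
    outside = sorted(set(universe) - set(target))
    if n_overlap > min(size, len(target)):
        raise ValueError("n_overlap exceeds size or the overlap set")
    if size - n_overlap > len(outside):
        raise ValueError("universe too small for the requested disjoint part")
    rng = _rng(rng_seed)
    inside = [target[i] for i in rng.choice(len(target), size=n_overlap, replace=False)] \
        if n_overlap else []
    rest = [outside[i] for i in rng.choice(len(outside), size=size - n_overlap, replace=False)] \
        if size > n_overlap else []
    return sorted(inside + rest)


def generate_scenario(
    n_nodes: int = 500,
    edges_per_node: int = 3,
    n_seeds: int = 20,
    n_connectors: int = 3,
    attach_fraction: float = 0.5,
    reference_size: int = 100,
    reference_overlap: int = 2,
    n_terms: int = 50,
    terms_per_gene: int = 3,
    rng_seed: int = 0,
) -> SyntheticScenario:
    """Convenience: a full default study — network, planted connectors,
    annotation with an enrichment block on the connectors' genes, and a
    reference list overlapping the connector genes."""
    ss = np.random.SeedSequence(rng_seed).spawn(4)
    net = generate_network(n_nodes, edges_per_node,
                           rng_seed=int(ss[0].generate_state(1)[0] % 2**31))
    scen = plant_connectors(net, n_seeds, n_connectors, attach_fraction,
                            rng_seed=int(ss[1].generate_state(1)[0] % 2**31))
    all_genes = scen.gene_map.genes()
    connector_genes = sorted("G_" + p for p in scen.true_connectors)
    scen.annotation = generate_annotation(
        all_genes, n_terms=n_terms, terms_per_gene=terms_per_gene,
        enriched_sets=[connector_genes],
        rng_seed=int(ss[2].generate_state(1)[0] % 2**31))
    # the reference cannot outgrow the synthetic gene universe: cap it so the
    # non-overlapping part always fits
    ref_size = min(reference_size, max(1, len(all_genes) // 3))
    scen.cancer_reference = generate_reference_list(
        all_genes, ref_size, overlap_with=connector_genes,
        n_overlap=min(reference_overlap, len(connector_genes), ref_size),
        rng_seed=int(ss[3].generate_state(1)[0] % 2**31))
    scen.generator_params.update({
        "edges_per_node": edges_per_node,
        "reference_size": reference_size,
        "reference_overlap": reference_overlap,
        "n_terms": n_terms,
        "terms_per_gene": terms_per_gene,
        "scenario_rng_seed": int(rng_seed),
    })
    return scen
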