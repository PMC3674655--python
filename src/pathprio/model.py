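"""Model/Results interface for shortest-path disease-gene prioritization.

``ShortestPathGeneModel`` holds the data — the weighted PPI network, the seed
genes and their protein mapping — and ``fit()`` runs the estimation: all-pairs
minimum-cost path mining among the resolved seed proteins, path-occurrence
betweenness tabulation, and the permutation null that turns counts into
empirical p-values. The returned ``ShortestPathGeneResults`` carries the
estimates (counts), their uncertainties (permutation p-values with a
supplementary BH column), the selected candidates, and diagnostics, with a
``summary()`` table and evaluation methods (reference-overlap test,
functional-profile similarity).

Example
-------
>>> from pathprio.simulate import generate_scenario
>>> from pathprio.model import ShortestPathGeneModel
>>> scen = generate_scenario(rng_seed=7)
>>> model = ShortestPathGeneModel(scen.network, scen.seeds, scen.gene_map)
>>> res = model.fit(n_perm=200, seed=1)
>>> print(res.summary())                               # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__ as _version
from .enrichment import DEFAULT_BACKGROUND, OverlapTest, overlap_test
from .network import (
    GeneProteinMap,
    PPINetwork,
    SeedResolution,
    build_network,
    read_string_edges,
    resolve_seed_proteins,
)
from .paths import (
    BetweennessTable,
    ShortestPathSet,
    all_pairs_seed_paths,
    betweenness_counts,
    write_betweenness,
    write_paths,
)
from .permutation import (
    PermutationConfig,
    PermutationResult,
    permutation_pvalues,
    select_candidates,
)
from .profiles import GOAnnotation, build_profile, profile_similarity

__all__ = ["ShortestPathGeneModel", "ShortestPathGeneResults"]


class ShortestPathGeneModel:
    """Prioritize disease genes by their occurrence on seed-to-seed
    minimum-cost paths in a weighted PPI network.

    Parameters
    ----------
    network
        Weighted undirected PPI network (confidence scores and traversal
        costs on edges).
    seed_genes
        Disease-associated gene symbols (e.g. members of a curated pathway).
        If ``gene_map`` is None they are taken to be protein identifiers
        already.
    gene_map
        One-to-many gene -> protein mapping; pair enumeration runs over the
        resolved proteins, so the pair count is C(m, 2) for m resolved
        proteins, not C(#genes, 2).
    include_seeds
        Keep seed nodes in the candidate table when they occur in the
        interior of other pairs' paths (default False).
    """

    def __init__(
        self,
        network: PPINetwork,
        seed_genes: Iterable[str],
        gene_map: GeneProteinMap | None = None,
        include_seeds: bool = False,
    ):
        self.network = network
        self.seed_genes = list(seed_genes)
        self.gene_map = gene_map
        self.include_seeds = include_seeds
        if gene_map is not None:
            self.resolution: SeedResolution | None = resolve_seed_proteins(
                self.seed_genes, gene_map, network)
            self.seed_proteins = sorted(self.resolution.proteins)
        else:
            self.resolution = None
            missing = [g for g in self.seed_genes if g not in network]
            if len(self.seed_genes) - len(missing) == 0:
                raise ValueError("no seed is a network node")
            self.seed_proteins = sorted(set(self.seed_genes) - set(missing))

    @classmethod
    def from_files(
        cls,
        edges_path: str,
        seeds_path: str,
        mapping_path: str | None = None,
        min_score: int = 0,
        **kwargs,
    ) -> "ShortestPathGeneModel":
        """Build the model from a STRING-style edge list, a one-gene-per-line
        seed file and an optional two-column mapping table."""
        edges = read_string_edges(edges_path, min_score=min_score)
        network = build_network(edges)
        seeds = [
            line.strip() for line in open(seeds_path) if line.strip()
        ]
        gm = GeneProteinMap.read(mapping_path) if mapping_path else None
        return cls(network, seeds, gm, **kwargs)

    def mine_paths(self) -> ShortestPathSet:
        """All-pairs minimum-cost paths among the resolved seed proteins."""
        return all_pairs_seed_paths(self.network, self.seed_proteins)

    def fit(
        self,
        n_perm: int = 2000,
        alpha: float = 0.05,
        seed: int = 0,
        sampling_universe: str = "network",
        exclude_observed_seeds: bool = False,
    ) -> "ShortestPathGeneResults":
        """Mine paths, tabulate betweenness, and run the permutation null.

        n_perm random equal-size seed sets are drawn from the sampling
        universe; each candidate's p-value is the fraction of replicates in
        which its count strictly exceeds the observed one. Candidates with
        p < alpha (strict) are selected.
        """
        path_set = self.mine_paths()
        observed = betweenness_counts(
            path_set, self.seed_proteins, include_seeds=self.include_seeds)
        config = PermutationConfig(
            n_perm=n_perm, alpha=alpha, rng_seed=seed,
            sampling_universe=sampling_universe,  # type: ignore[arg-type]
            exclude_observed_seeds=exclude_observed_seeds,
        )
        mapped_nodes = None
        if sampling_universe == "mapped":
            if self.gene_map is None:
                raise ValueError("sampling_universe='mapped' needs a gene map")
            mapped_nodes = set().union(*(self.gene_map[g] for g in self.gene_map.genes()))
        perm = permutation_pvalues(
            self.network, observed, seed_size=len(self.seed_proteins),
            config=config, observed_seeds=self.seed_proteins,
            mapped_nodes=mapped_nodes,
        )
        selected = select_candidates(perm, alpha)
        return ShortestPathGeneResults(
            model=self, path_set=path_set, betweenness=observed,
            permutation=perm, selected=selected, config=config,
        )


@dataclass
class ShortestPathGeneResults:
    """Fitted results: mined paths, counts, permutation p-values, selection."""

    model: ShortestPathGeneModel
    path_set: ShortestPathSet
    betweenness: BetweennessTable
    permutation: PermutationResult
    selected: list[str]
    config: PermutationConfig
    _sig: pd.DataFrame | None = field(default=None, repr=False)

    # -- estimates -----------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Per-candidate observed count, exceedance, p-value and BH column."""
        return self.permutation.table

    @property
    def pvalues(self) -> pd.Series:
        return self.permutation.p_values

    @property
    def n_paths(self) -> int:
        return len(self.path_set)

    @property
    def n_path_genes(self) -> int:
        return len(self.betweenness)

    def candidate_table(self) -> pd.DataFrame:
        """Selected candidates ordered by (p, -observed, id)."""
        return self.table.loc[self.selected]

    # -- evaluation ----------------------------------------------------------
    def overlap_with_reference(
        self, reference: Iterable[str], background: int = DEFAULT_BACKGROUND,
        as_genes: bool = True,
    ) -> OverlapTest:
        """Strict-tail hypergeometric overlap between the selected
        candidates and a reference gene list."""
        cands = self.selected_genes() if as_genes else self.selected
        return overlap_test(cands, reference, N=background)

    def functional_similarity(
        self, reference: Iterable[str], annotation: GOAnnotation,
        as_genes: bool = True,
    ) -> float:
        """Pearson correlation of the candidates' and the reference's GO
        functional profiles over the annotation's full term universe."""
        cands = self.selected_genes() if as_genes else self.selected
        prof_c = build_profile(cands, annotation)
        prof_r = build_profile(reference, annotation)
        return profile_similarity(prof_c, prof_r)

    def selected_genes(self) -> list[str]:
        """Selected candidates as gene symbols, via the reverse mapping when
        a gene map is present (max-count convention upstream; here a protein
        maps to every gene symbol that lists it)."""
        gm = self.model.gene_map
        if gm is None:
            return list(self.selected)
        rev: dict[str, list[str]] = {}
        for gene, prots in gm.items():
            for p in prots:
                rev.setdefault(p, []).append(gene)
        out: list[str] = []
        for prot in self.selected:
            out.extend(rev.get(prot, [prot]))
        seen: set[str] = set()
        return [g for g in out if not (g in seen or seen.add(g))]

    # -- reporting -----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "Shortest-path gene prioritization",
            "=" * 49,
            f"network nodes / edges : {len(m.network)} / {m.network.n_edges}",
            f"seed genes / proteins : {len(m.seed_genes)} / {len(m.seed_proteins)}",
            f"seed pairs            : {self.path_set.n_pairs}"
            f"  (paths {self.n_paths}, unreachable {len(self.path_set.skipped_pairs)})",
            f"path genes            : {self.n_path_genes}",
            f"permutations          : {self.permutation.n_perm}"
            f"  (alpha {self.config.alpha}, rng seed {self.config.rng_seed})",
            f"selected candidates   : {len(self.selected)} with p < {self.config.alpha}",
            "-" * 49,
            f"{'id':<16}{'observed':>9}{'exceed':>8}{'p':>10}{'BH p':>10}",
        ]
        for g in self.selected[:top]:
            row = self.table.loc[g]
            lines.append(
                f"{g:<16}{int(row.observed):>9}{int(row.exceed):>8}"
                f"{row.p_value:>10.4g}{row.bh_p:>10.4g}"
            )
        if len(self.selected) > top:
            lines.append(f"... ({len(self.selected) - top} more)")
        lines.append("-" * 49)
        lines.append("p = 0 means no replicate exceeded the observed count "
                      f"(report as < {1.0 / self.permutation.n_perm:g})")
        return "\n".join(lines)

    def to_files(self, outdir: str | Path) -> None:
        """Write paths, betweenness and permutation tables as TSV."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "paths.tsv", "w") as fh:
            write_paths(self.path_set, fh)
        with open(out / "betweenness.tsv", "w") as fh:
            write_betweenness(self.betweenness, fh)
        with open(out / "permutation.tsv", "w") as fh:
            self.permutation.write(fh)
        with open(out / "candidates.txt", "w") as fh:
            fh.write("\n".join(self.selected) + ("\n" if self.selected else ""))
        (out / "VERSION").write_text(_version + "\n")
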