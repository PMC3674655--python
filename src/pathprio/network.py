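"""Weighted protein-protein interaction networks from STRING-style edge lists.

STRING scores interactions with an integer confidence in [1, 999]; higher
means more confident. For shortest-path mining the score is converted into a
positive traversal cost that decreases as confidence grows, so that paths
through strongly supported interactions are cheap. The default transform is
``cost = 1000 - score``, mapping the score range onto integer costs [1, 999].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, TextIO

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

SCORE_MIN = 1
SCORE_MAX = 999

__all__ = [
    "ConfidenceEdge",
    "PPINetwork",
    "GeneProteinMap",
    "SeedResolution",
    "confidence_to_cost",
    "read_string_edges",
    "build_network",
    "resolve_seed_proteins",
    "write_network",
]


class EdgeParseError(ValueError):
    """Raised when an interaction row cannot be parsed."""


@dataclass(frozen=True, order=True)
class ConfidenceEdge:
    """An undirected interaction with a STRING-style confidence score.

    Endpoints are stored in canonical (sorted) order so the unordered pair
    has a single representation.
    """

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-loop edge on {self.protein_a!r}")
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ValueError(
                f"confidence score {self.score} outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def confidence_to_cost(score: int) -> float:
    """Map a confidence score in [1, 999] to a traversal cost ``1000 - score``.

    Strictly positive and strictly decreasing in the score: the strongest
    supported interaction (999) costs 1, the weakest (1) costs 999.
    """
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"confidence score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return float(1000 - score)


def read_string_edges(
    source: str | TextIO | Iterable[str],
    min_score: int = 0,
) -> list[ConfidenceEdge]:
    """Parse a STRING ``protein.links``-style tab/space-separated edge list.

    Expects at least three columns per data row: protein_a, protein_b,
    combined score. A header line is auto-detected (score column fails to
    parse as an integer on the first line only). Duplicate unordered pairs
    keep the maximum score; self-loops are dropped (counted in the log).

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines.
    min_score
        Drop edges with score strictly below this value (default 0: keep all).

    Returns
    -------
    list of ConfidenceEdge, canonical and deduplicated, sorted.
    """
    close = False
    if isinstance(source, str):
        handle: Iterable[str] = open(source, "rt")
        close = True
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        handle = source
    else:
        handle = source

    best: dict[tuple[str, str], int] = {}
    n_self = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise EdgeParseError(f"line {lineno}: expected >= 3 columns, got {len(parts)}")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = int(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise EdgeParseError(f"line {lineno}: score {raw!r} is not an integer") from None
            if not (SCORE_MIN <= score <= SCORE_MAX):
                raise EdgeParseError(
                    f"line {lineno}: score {score} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]

    if n_self:
        logger.info("dropped %d self-loop row(s)", n_self)
    edges = [
        ConfidenceEdge(a, b, s) for (a, b), s in sorted(best.items()) if s >= min_score
    ]
    return edges


class PPINetwork:
    """Weighted undirected PPI network.

    Wraps a :class:`networkx.Graph` whose edges carry ``score`` (integer
    confidence) and ``cost`` (positive traversal weight). A compiled sparse
    representation for fast shortest-path work is built lazily and cached;
    any mutation of the underlying graph must go through :meth:`invalidate`.
    """

    def __init__(self, graph: nx.Graph, cost_fn: Callable[[int], float] = confidence_to_cost):
        self.graph = graph
        self.cost_fn = cost_fn
        self._compiled: _CompiledNetwork | None = None

    # -- container-ish surface -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def invalidate(self) -> None:
        """Drop the cached compiled form after mutating ``self.graph``."""
        self._compiled = None

    def compiled(self) -> "_CompiledNetwork":
        if self._compiled is None:
            self._compiled = _CompiledNetwork.from_graph(self.graph)
        return self._compiled

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.graph.copy(), self.cost_fn)

    def set_edge_score(self, a: str, b: str, score: int) -> None:
        """Add or overwrite an edge with the given confidence score."""
        if a == b:
            raise ValueError("self-loop")
        cost = self.cost_fn(score)
        if cost <= 0:
            raise ValueError("cost transform must return positive costs")
        self.graph.add_edge(a, b, score=score, cost=cost)
        self.invalidate()


def build_network(
    edges: Iterable[ConfidenceEdge],
    cost_fn: Callable[[int], float] = confidence_to_cost,
) -> PPINetwork:
    """Assemble the weighted undirected network from canonical edges.

    The node set is the union of edge endpoints; each edge carries its score
    and the derived cost. An empty edge list yields an empty network (with a
    warning), not an error.
    """
    g = nx.Graph()
    n = 0
    for e in edges:
        cost = cost_fn(e.score)
        if cost <= 0:
            raise ValueError(f"cost transform returned non-positive cost for score {e.score}")
        g.add_edge(e.protein_a, e.protein_b, score=e.score, cost=cost)
        n += 1
    if n == 0:
        logger.warning("building an empty network: no edges supplied")
    return PPINetwork(g, cost_fn)


def write_network(network: PPINetwork, handle: TextIO) -> None:
    """Write a canonical sorted edge list: node_a, node_b, score, cost."""
    rows = []
    for a, b, data in network.graph.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        rows.append((a, b, data["score"], data["cost"]))
    handle.write("protein_a\tprotein_b\tscore\tcost\n")
    for a, b, score, cost in sorted(rows):
        handle.write(f"{a}\t{b}\t{score}\t{cost:g}\n")


class GeneProteinMap:
    """One-to-many gene symbol -> protein identifier mapping.

    Looking up an unmapped gene raises ``KeyError`` rather than returning an
    empty set, so a missing annotation is always a detectable condition.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None):
        self._entries: dict[str, frozenset[str]] = {}
        if entries:
            for gene, prots in entries.items():
                self.add(gene, prots)

    def add(self, gene: str, proteins: Iterable[str] | str) -> None:
        if isinstance(proteins, str):
            proteins = [proteins]
        new = frozenset(proteins)
        if not new:
            raise ValueError(f"gene {gene!r} mapped to an empty protein set")
        self._entries[gene] = self._entries.get(gene, frozenset()) | new

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self._entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def genes(self) -> list[str]:
        return sorted(self._entries)

    def items(self):
        return self._entries.items()

    def proteins_for(self, gene: str) -> frozenset[str]:
        """Alias for ``map[gene]``; raises KeyError if unmapped."""
        return self._entries[gene]

    @classmethod
    def read(cls, source: str | TextIO) -> "GeneProteinMap":
        """Read a two-column tab-separated gene->protein table.

        Repeated rows for the same gene accumulate into its protein set.
        A header row is auto-detected if the first line's columns are named
        'gene' and 'protein' (case-insensitive prefix match).
        """
        close = isinstance(source, str)
        handle = open(source, "rt") if close else source
        gm = cls()
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"line {lineno}: expected 2 columns")
                if lineno == 1 and parts[0].lower().startswith("gene"):
                    continue
                gm.add(parts[0], parts[1])
        finally:
            if close:
                handle.close()
        return gm

    def write(self, handle: TextIO) -> None:
        handle.write("gene\tprotein\n")
        for gene in sorted(self._entries):
            for prot in sorted(self._entries[gene]):
                handle.write(f"{gene}\t{prot}\n")


@dataclass
class SeedResolution:
    """Outcome of mapping seed gene symbols onto network nodes."""

    proteins: frozenset[str]
    unmapped_genes: tuple[str, ...] = ()
    absent_proteins: tuple[str, ...] = ()
    gene_to_resolved: dict[str, frozenset[str]] = field(default_factory=dict)


def resolve_seed_proteins(
    genes: Iterable[str],
    gene_map: GeneProteinMap,
    network: PPINetwork,
) -> SeedResolution:
    """Map seed gene symbols to in-network protein identifiers.

    Returns the union of mapped proteins restricted to network nodes,
    together with a report of unmapped genes and mapped-but-absent proteins.
    Because the mapping is one-to-many, the resolved protein count can exceed
    the gene count; downstream pair enumeration runs over resolved proteins.

    Raises
    ------
    ValueError
        If the gene list is empty or no gene resolves to any network node.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty seed gene list")
    resolved: set[str] = set()
    unmapped: list[str] = []
    absent: set[str] = set()
    per_gene: dict[str, frozenset[str]] = {}
    nodes = network.graph
    for gene in genes:
        if gene not in gene_map:
            unmapped.append(gene)
            continue
        prots = gene_map[gene]
        here = frozenset(p for p in prots if p in nodes)
        absent.update(prots - here)
        per_gene[gene] = here
        resolved.update(here)
    if not resolved:
        raise ValueError(
            f"none of the {len(genes)} seed genes resolve to a network protein"
        )
    if unmapped:
        logger.info("%d seed gene(s) had no protein mapping: %s", len(unmapped), unmapped)
    if absent:
        logger.info("%d mapped protein(s) absent from the network", len(absent))
    return SeedResolution(
        proteins=frozenset(resolved),
        unmapped_genes=tuple(unmapped),
        absent_proteins=tuple(sorted(absent)),
        gene_to_resolved=per_gene,
    )


class _CompiledNetwork:
    """Sparse compiled form of a PPINetwork for shortest-path work.

    Nodes are sorted by identifier so index order coincides with the
    lexicographic order used for deterministic tie-breaking. Neighbor lists
    are pre-sorted by index.
    """

    __slots__ = ("labels", "index", "csr", "indptr", "indices", "costs", "n")

    def __init__(self, labels, index, csr):
        self.labels = labels
        self.index = index
        self.csr = csr
        self.indptr = csr.indptr
        self.indices = csr.indices
        self.costs = csr.data
        self.n = len(labels)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "_CompiledNetwork":
        labels = sorted(graph.nodes)
        index = {lab: i for i, lab in enumerate(labels)}
        rows, cols, data = [], [], []
        for a, b, d in graph.edges(data=True):
            ia, ib = index[a], index[b]
            c = float(d["cost"])
            rows.append(ia); cols.append(ib); data.append(c)
            rows.append(ib); cols.append(ia); data.append(c)
        n = len(labels)
        csr = csr_matrix(
            (np.asarray(data), (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
            shape=(n, n),
        )
        csr.sort_indices()
        return cls(labels, index, csr)
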