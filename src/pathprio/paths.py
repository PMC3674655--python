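"""Minimum-cost path mining between seed proteins and path-occurrence counts.

The statistic of interest is not classical betweenness centrality: for each
unordered pair of seed proteins exactly one minimum-cost path is mined, and a
gene's "betweenness" is the number of those paths whose interior contains it.
Among equal-cost optima the lexicographically smallest node sequence (under
sorted-identifier order) is returned, making runs byte-reproducible where the
underlying graph libraries would return an arbitrary optimum.

Distances come from scipy's sparse Dijkstra; the deterministic path is then
extracted by a greedy walk on the shortest-path DAG: from the current node,
step to the smallest-labelled neighbor v satisfying
``dist_s(u) + w(u, v) + dist_t(v) == dist_s(t)``. Edge costs are positive, so
``dist_t`` strictly decreases along the walk and the path is simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .network import PPINetwork, _CompiledNetwork

__all__ = [
    "ShortestPath",
    "ShortestPathSet",
    "BetweennessTable",
    "dijkstra_path",
    "all_pairs_seed_paths",
    "betweenness_counts",
    "write_paths",
    "write_betweenness",
]

# Relative slack for cost-equality checks on the shortest-path DAG. The
# default confidence transform yields integer costs, for which float sums are
# exact; the slack only matters for user-supplied real-valued transforms.
_REL_TOL = 1e-9


@dataclass(frozen=True)
class ShortestPath:
    source: str
    target: str
    nodes: tuple[str, ...]
    cost: float

    @property
    def interior(self) -> tuple[str, ...]:
        return self.nodes[1:-1]


@dataclass
class ShortestPathSet:
    """One minimum-cost path per connected unordered seed pair."""

    paths: list[ShortestPath]
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    seeds: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def n_pairs(self) -> int:
        return len(self.paths) + len(self.skipped_pairs)


@dataclass
class BetweennessTable:
    """Per-node path-occurrence counts on the mined paths."""

    counts: dict[str, int]

    def __getitem__(self, node: str) -> int:
        return self.counts.get(node, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def items(self):
        return self.counts.items()

    def ranked(self) -> list[tuple[str, int]]:
        """(node, count) sorted by count descending, then identifier."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _distances(comp: _CompiledNetwork, sources: np.ndarray) -> np.ndarray:
    if comp.n == 0 or len(sources) == 0:
        return np.empty((len(sources), comp.n))
    return _sp_dijkstra(comp.csr, directed=True, indices=sources)


def _extract_path(
    comp: _CompiledNetwork,
    s: int,
    t: int,
    dist_s: np.ndarray,
    dist_t: np.ndarray,
) -> list[int] | None:
    """Lexicographically smallest node-index sequence among optimal s-t paths."""
    total = dist_s[t]
    if not np.isfinite(total):
        return None
    if s == t:
        return [s]
    tol = _REL_TOL * max(1.0, total)
    indptr, indices, costs = comp.indptr, comp.indices, comp.costs
    path = [s]
    u = s
    while u != t:
        du = dist_s[u]
        lo, hi = indptr[u], indptr[u + 1]
        nxt = -1
        for k in range(lo, hi):
            v = indices[k]
            if abs(du + costs[k] + dist_t[v] - total) <= tol:
                nxt = v
                break  # neighbors sorted by index == label order
        if nxt < 0:  # cannot happen on a consistent DAG
            raise RuntimeError("shortest-path DAG inconsistency during extraction")
        path.append(nxt)
        u = nxt
    return path


def dijkstra_path(network: PPINetwork, source: str, target: str) -> ShortestPath | None:
    """Minimum-cost path between two nodes, or None if unreachable.

    Among equal-cost optima the lexicographically smallest node sequence is
    returned. ``source == target`` yields the single-node path of cost 0.
    """
    comp = network.compiled()
    for node in (source, target):
        if node not in comp.index:
            raise KeyError(f"node {node!r} not in network")
    si, ti = comp.index[source], comp.index[target]
    if si == ti:
        return ShortestPath(source, target, (source,), 0.0)
    dists = _distances(comp, np.array([si, ti]))
    idx_path = _extract_path(comp, si, ti, dists[0], dists[1])
    if idx_path is None:
        return None
    return ShortestPath(
        source, target, tuple(comp.labels[i] for i in idx_path), float(dists[0][ti])
    )


def all_pairs_seed_paths(network: PPINetwork, seeds: Iterable[str]) -> ShortestPathSet:
    """Mine one minimum-cost path per unordered pair of seed proteins.

    Pairs are enumerated in sorted order; unreachable pairs are recorded in
    ``skipped_pairs`` rather than raising, since large interaction networks
    can be disconnected.
    """
    seed_list = sorted(set(seeds))
    if len(seed_list) < 2:
        raise ValueError("need at least 2 seed proteins")
    comp = network.compiled()
    missing = [s for s in seed_list if s not in comp.index]
    if missing:
        raise KeyError(f"seed protein(s) not in network: {missing}")
    sidx = np.array([comp.index[s] for s in seed_list])
    dists = _distances(comp, sidx)
    paths: list[ShortestPath] = []
    skipped: list[tuple[str, str]] = []
    for (i, a), (j, b) in combinations(enumerate(seed_list), 2):
        idx_path = _extract_path(comp, sidx[i], sidx[j], dists[i], dists[j])
        if idx_path is None:
            skipped.append((a, b))
        else:
            paths.append(
                ShortestPath(a, b, tuple(comp.labels[k] for k in idx_path),
                             float(dists[i][sidx[j]]))
            )
    return ShortestPathSet(paths=paths, skipped_pairs=skipped, seeds=frozenset(seed_list))


def betweenness_counts(
    path_set: ShortestPathSet,
    seeds: Iterable[str] | None = None,
    include_seeds: bool = False,
) -> BetweennessTable:
    """Count, per node, the mined paths whose interior contains it.

    Endpoints never count. With ``include_seeds=False`` (default) seed nodes
    are removed from the resulting table even when they sit in the interior
    of some other pair's path, so the table lists candidate (non-seed) genes
    only.
    """
    seed_set = frozenset(seeds) if seeds is not None else path_set.seeds
    counts: dict[str, int] = {}
    for p in path_set.paths:
        for node in p.interior:
            counts[node] = counts.get(node, 0) + 1
    if not include_seeds:
        for s in seed_set:
            counts.pop(s, None)
    return BetweennessTable(counts)


def collapse_to_genes(
    table: BetweennessTable, protein_to_genes: dict[str, Sequence[str]]
) -> BetweennessTable:
    """Collapse protein-level counts to gene symbols, keeping the maximum
    count over a gene's proteins. Proteins without a gene keep their own ID."""
    out: dict[str, int] = {}
    for prot, c in table.items():
        for g in protein_to_genes.get(prot, (prot,)):
            if c > out.get(g, -1):
                out[g] = c
    return BetweennessTable(out)


# -- mined-path tabular output (source, target, cost, node sequence) ---------

def write_paths(path_set: ShortestPathSet, handle: TextIO) -> None:
    handle.write("source\ttarget\tcost\tnodes\n")
    for p in path_set.paths:
        handle.write(f"{p.source}\t{p.target}\t{p.cost:g}\t{'|'.join(p.nodes)}\n")
    for a, b in path_set.skipped_pairs:
        handle.write(f"{a}\t{b}\tNA\tUNREACHABLE\n")


def write_betweenness(table: BetweennessTable, handle: TextIO) -> None:
    handle.write("id\tcount\n")
    for node, c in table.ranked():
        handle.write(f"{node}\t{c}\n")


# -- fast count-only mining used by the permutation engine -------------------

def _py_pair_counts(comp: _CompiledNetwork, seed_idx: np.ndarray,
                    dists: np.ndarray) -> np.ndarray:
    counts = np.zeros(comp.n, dtype=np.int64)
    m = len(seed_idx)
    for i in range(m):
        di = dists[i]
        for j in range(i + 1, m):
            p = _extract_path(comp, seed_idx[i], seed_idx[j], di, dists[j])
            if p is not None and len(p) > 2:
                counts[p[1:-1]] += 1
    return counts


try:  # optional numba kernel: same greedy walk, compiled
    import numba

    @numba.njit(cache=True)
    def _nb_pair_counts(indptr, indices, costs, dists, seed_idx, n):  # pragma: no cover
        counts = np.zeros(n, dtype=np.int64)
        m = len(seed_idx)
        for i in range(m):
            for j in range(i + 1, m):
                s = seed_idx[i]
                t = seed_idx[j]
                dist_s = dists[i]
                dist_t = dists[j]
                total = dist_s[t]
                if not np.isfinite(total):
                    continue
                tol = 1e-9 * max(1.0, total)
                u = s
                steps = 0
                while u != t and steps <= n:
                    du = dist_s[u]
                    nxt = -1
                    for k in range(indptr[u], indptr[u + 1]):
                        v = indices[k]
                        if abs(du + costs[k] + dist_t[v] - total) <= tol:
                            nxt = v
                            break
                    if nxt < 0:
                        break
                    if nxt != t:
                        counts[nxt] += 1
                    u = nxt
                    steps += 1
        return counts

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba genuinely absent
    _HAVE_NUMBA = False


def _mine_interior_counts(
    comp: _CompiledNetwork, seed_idx: np.ndarray, force_python: bool = False
) -> np.ndarray:
    """Interior occurrence counts (per node index) over all seed-pair paths.

    Shares the greedy tie-break with :func:`all_pairs_seed_paths`, so the
    counts equal ``betweenness_counts(..., include_seeds=True)`` restricted
    to indices; unreachable pairs contribute nothing. Runs through a numba
    kernel when available (the pure-Python route is equivalent and kept as
    the reference implementation).
    """
    seed_idx = np.sort(np.asarray(seed_idx))
    dists = _distances(comp, seed_idx)
    if _HAVE_NUMBA and not force_python:
        return _nb_pair_counts(
            comp.indptr, comp.indices, comp.costs, dists,
            seed_idx.astype(np.int64), comp.n)
    return _py_pair_counts(comp, seed_idx, dists)
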