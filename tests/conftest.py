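import io

import networkx as nx
import numpy as np
import pytest

from pathprio.network import ConfidenceEdge, PPINetwork, build_network


@pytest.fixture
def triangle_network() -> PPINetwork:
    """A, B, C with costs A-B=1, B-C=1, A-C=900."""
    return build_network([
        ConfidenceEdge("A", "B", 999),
        ConfidenceEdge("B", "C", 999),
        ConfidenceEdge("A", "C", 100),
    ])


@pytest.fixture
def star_network() -> PPINetwork:
    """Hub H with six leaves L1..L6, all edges cost 1."""
    return build_network(
        [ConfidenceEdge("H", f"L{i}", 999) for i in range(1, 7)]
    )


def random_weighted_network(rng: np.random.Generator, n_max: int = 8) -> PPINetwork:
    """Small random connected weighted graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    while True:
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            break
    edges = [
        ConfidenceEdge(f"N{a}", f"N{b}", int(rng.integers(1, 1000)))
        for a, b in g.edges()
    ]
    return build_network(edges)


def brute_force_cost(network: PPINetwork, source: str, target: str) -> float | None:
    """Exhaustive minimum cost over all simple paths (independent oracle)."""
    g = network.graph
    best = None
    for path in nx.all_simple_paths(g, source, target):
        c = sum(g[u][v]["cost"] for u, v in zip(path, path[1:]))
        if best is None or c < best:
            best = c
    return best


def as_handle(text: str) -> io.StringIO:
    return io.StringIO(text)
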