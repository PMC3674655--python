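"""Permutation significance of path-occurrence betweenness.

A candidate's observed count could simply reflect its being a hub of the
background network rather than anything seed-specific. The null model
re-mines all-pairs shortest paths for random seed sets of the same size and
asks how often a candidate's count under the null strictly exceeds its
observed count. The empirical p-value is that proportion:

    p(g) = #{ j : b_j(g) > b_obs(g) } / n_perm

Strict exceedance means p = 0 is attainable; report such values as
"< 1/n_perm" when communicating results. No pseudocount is added and no
multiple-testing correction is applied to the selection rule (a
Benjamini-Hochberg column is emitted as supplementary information only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .network import PPINetwork
from .paths import BetweennessTable, _mine_interior_counts

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "permutation_pvalues",
    "exhaustive_pvalues",
    "select_candidates",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation null.

    n_perm: number of random seed sets (replicates); default 2000.
    alpha: selection threshold on the empirical p-value; default 0.05, strict.
    rng_seed: seed for the replicate sampler; replicates draw from
        independent spawned substreams, so results do not depend on
        evaluation order.
    sampling_universe: "network" draws random seeds from all network nodes;
        "mapped" restricts to nodes carrying a gene mapping.
    exclude_observed_seeds: drop the original seed proteins from the
        sampling universe (off by default).
    """

    n_perm: int = 2000
    alpha: float = 0.05
    rng_seed: int = 0
    sampling_universe: Literal["network", "mapped"] = "network"
    exclude_observed_seeds: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PermutationResult:
    """Per-candidate observed counts, exceedance counts and p-values."""

    table: pd.DataFrame  # index: candidate id; columns observed, exceed, p_value, bh_p
    n_perm: int
    config: PermutationConfig | None = field(default=None, repr=False)

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    def write(self, handle: TextIO) -> None:
        out = self.table.reset_index(names="id")
        out.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def _candidate_universe(
    network: PPINetwork,
    config: PermutationConfig,
    observed_seeds: Iterable[str] | None,
    mapped_nodes: Iterable[str] | None,
) -> list[str]:
    if config.sampling_universe == "mapped":
        if mapped_nodes is None:
            raise ValueError("sampling_universe='mapped' requires mapped_nodes")
        universe = sorted(set(mapped_nodes) & network.nodes)
    else:
        universe = sorted(network.nodes)
    if config.exclude_observed_seeds and observed_seeds is not None:
        drop = set(observed_seeds)
        universe = [u for u in universe if u not in drop]
    return universe


def _assemble(observed: pd.Series, exceed: np.ndarray, n_perm: int,
              config: PermutationConfig | None) -> PermutationResult:
    p = exceed / n_perm
    bh = stats.false_discovery_control(p, method="bh") if len(p) else np.array([])
    table = pd.DataFrame(
        {
            "observed": observed.astype(int),
            "exceed": exceed.astype(int),
            "p_value": p,
            "bh_p": bh,
        },
        index=observed.index,
    )
    table.index.name = "id"
    return PermutationResult(table=table, n_perm=n_perm, config=config)


def permutation_pvalues(
    network: PPINetwork,
    candidates: BetweennessTable,
    seed_size: int,
    config: PermutationConfig,
    observed_seeds: Iterable[str] | None = None,
    mapped_nodes: Iterable[str] | None = None,
) -> PermutationResult:
    """Empirical p-values for candidate betweenness under random seed sets.

    Each replicate draws ``seed_size`` nodes uniformly without replacement
    from the sampling universe, mines all-pairs minimum-cost paths with the
    same machinery as the observed run (same tie-break, same skip rule for
    unreachable pairs), counts each candidate's interior occurrences, and
    tallies strict exceedances of the observed count.

    Fully reproducible from ``config.rng_seed``: replicate j uses the j-th
    spawned child of ``SeedSequence(rng_seed)``.
    """
    if seed_size < 2:
        raise ValueError("seed_size must be >= 2")
    if len(candidates) == 0:
        raise ValueError("no candidates supplied")
    comp = network.compiled()
    universe = _candidate_universe(network, config, observed_seeds, mapped_nodes)
    if seed_size > len(universe):
        raise ValueError(
            f"seed_size {seed_size} exceeds sampling universe of {len(universe)}"
        )
    uni_idx = np.array([comp.index[u] for u in universe])

    cand_ids = sorted(candidates.counts)
    cand_idx = np.array([comp.index[c] for c in cand_ids if c in comp.index])
    cand_ids = [c for c in cand_ids if c in comp.index]
    observed = pd.Series({c: candidates[c] for c in cand_ids}, dtype=int)
    obs_arr = observed.to_numpy()

    exceed = np.zeros(len(cand_ids), dtype=np.int64)
    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_perm)
    for child in children:
        rng = np.random.default_rng(child)
        draw = uni_idx[rng.choice(len(uni_idx), size=seed_size, replace=False)]
        counts = _mine_interior_counts(comp, draw)
        # a replicate seed node's interior occurrences elsewhere still count,
        # mirroring the observed run's include_seeds=False only for *its own*
        # seeds; candidates are fixed nodes here, so no removal is needed.
        exceed += counts[cand_idx] > obs_arr
    return _assemble(observed, exceed, config.n_perm, config)


def exhaustive_pvalues(
    network: PPINetwork,
    candidates: BetweennessTable,
    seed_size: int,
    universe: Iterable[str] | None = None,
) -> PermutationResult:
    """Exact null by enumerating every size-``seed_size`` subset of the
    universe instead of sampling. Only feasible for tiny networks; serves as
    the reference the sampled estimator converges to."""
    comp = network.compiled()
    uni = sorted(universe) if universe is not None else sorted(network.nodes)
    uni_idx = [comp.index[u] for u in uni]
    cand_ids = sorted(c for c in candidates.counts if c in comp.index)
    cand_idx = np.array([comp.index[c] for c in cand_ids])
    observed = pd.Series({c: candidates[c] for c in cand_ids}, dtype=int)
    obs_arr = observed.to_numpy()
    exceed = np.zeros(len(cand_ids), dtype=np.int64)
    n_sets = 0
    for subset in combinations(uni_idx, seed_size):
        counts = _mine_interior_counts(comp, np.array(subset))
        exceed += counts[cand_idx] > obs_arr
        n_sets += 1
    return _assemble(observed, exceed, n_sets, None)


def null_calibration_pvalues(
    network: PPINetwork,
    seed_size: int,
    n_trials: int = 200,
    n_perm: int = 200,
    rng_seed: int = 0,
    candidate: str | None = None,
) -> np.ndarray:
    """Empirical p-values for a candidate whose observed count is itself
    drawn from the null process.

    Each trial draws its own random seed set, takes the candidate's interior
    count on that set's paths as "observed", and computes the permutation
    p-value against ``n_perm`` fresh replicates. When the null holds the
    p-values should be approximately Uniform(0, 1); with a discrete count
    distribution the strict-exceedance p is sub-uniform by at most the
    largest point mass, so the candidate defaults to the maximum-degree node,
    whose occurrence distribution is spread over many values.
    """
    comp = network.compiled()
    if candidate is None:
        degrees = dict(network.graph.degree())
        candidate = max(sorted(degrees), key=lambda n: degrees[n])
    cand_idx = comp.index[candidate]
    uni_idx = np.arange(comp.n)
    pvals = np.empty(n_trials)
    trial_seeds = np.random.SeedSequence(rng_seed).spawn(n_trials)
    for t, tseed in enumerate(trial_seeds):
        children = tseed.spawn(n_perm + 1)
        rng = np.random.default_rng(children[0])
        draw = uni_idx[rng.choice(comp.n, size=seed_size, replace=False)]
        observed = _mine_interior_counts(comp, draw)[cand_idx]
        exceed = 0
        for child in children[1:]:
            rng_j = np.random.default_rng(child)
            d = uni_idx[rng_j.choice(comp.n, size=seed_size, replace=False)]
            exceed += _mine_interior_counts(comp, d)[cand_idx] > observed
        pvals[t] = exceed / n_perm
    return pvals


def select_candidates(result: PermutationResult, alpha: float = 0.05) -> list[str]:
    """Candidates with p-value strictly below alpha, ordered by
    (p ascending, observed descending, identifier)."""
    t = result.table
    hits = t[t["p_value"] < alpha]
    order = sorted(hits.index, key=lambda g: (hits.at[g, "p_value"], -hits.at[g, "observed"], g))
    return order
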