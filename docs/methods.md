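# Methods

## Model

`pathprio` treats disease-gene prioritization as a network-intermediacy
problem. The data are an undirected protein–protein interaction graph whose
edges carry integer confidence scores s ∈ [1, 999], a one-to-many map from
gene symbols to protein nodes, and a list of seed genes. The estimand is,
for every non-seed gene g, a path-occurrence count

    b(g) = #{ seed pairs (i, j) : g lies in the interior of the mined
              minimum-cost i–j path }

together with an empirical significance against the null hypothesis that
b(g) is no larger than what equally-sized *random* node sets would produce.
The underlying assumption is the guilt-by-association principle: proteins
that mediate many cheapest routes between disease proteins are likely to be
functionally involved themselves. The test deliberately separates
seed-specific intermediacy from mere hubness — a hub lies on many paths for
*any* node set, so it earns no significance.

### Confidence-to-cost transform

Costs are w = 1000 − s, mapping the score scale onto integer costs
[1, 999], strictly positive and strictly decreasing in confidence. The
transform is exposed as a parameter of network construction
(`build_network(..., cost_fn=...)`); any strictly positive decreasing
function is accepted. Integer costs have the practical advantage that path
costs are exact in floating point, making the equal-cost tie-break below
well defined without tolerance tuning (a 1e-9 relative slack guards
user-supplied real-valued transforms).

### One path per pair and the deterministic tie-break

Exactly one minimum-cost path is mined per unordered seed pair, so the path
count for m resolved seed proteins is C(m, 2) minus unreachable pairs
(unreachable pairs are recorded and skipped, not errors — interactome-scale
graphs are disconnected). Minimum-cost paths are frequently non-unique;
generic implementations return an arbitrary optimum, which makes counts
non-reproducible across library versions. We return the lexicographically
smallest node sequence among the optima: distances d_s, d_t to both
endpoints come from sparse Dijkstra (scipy), and the path is extracted by a
greedy walk that, at each node u, steps to the smallest-labelled neighbor v
with d_s(u) + w(u, v) + d_t(v) equal to the optimal total. Because all
costs are positive, d_t strictly decreases along the walk, so the result is
a simple path; a short induction shows the greedy choice yields the
lexicographic minimum over all optimal sequences. The count-only variant of
this walk used inside the permutation loop is compiled with numba; the pure
Python route is kept as the reference implementation and the two are
asserted equal in the test suite.

Seed nodes can appear in the interior of *other* pairs' paths. By default
they are removed from the candidate table (candidates are new genes, not
seeds); a flag keeps them. With seeds included, interior counts obey the
conservation identity Σ_g b(g) = Σ_paths (|nodes| − 2), which the tests
check on every random instance.

## Permutation null

Each replicate draws `seed_size` nodes uniformly without replacement from
the sampling universe (default: all network nodes; optionally only mapped
nodes, optionally excluding the observed seeds), re-mines all pairs with the
identical machinery — same tie-break, same skip rule — and records each
candidate's interior count. The p-value is the strict-exceedance proportion
p(g) = #{j : b_j(g) > b(g)} / n_perm with no pseudocount, so p = 0 is
attainable and is reported as "< 1/n_perm". Selection is strict: p < α.
No multiple-testing correction enters the selection; a Benjamini–Hochberg
column is emitted for information. Replicates draw from independent spawned
substreams of the seeded generator, so results are identical regardless of
evaluation order. Defaults: n_perm = 2000, α = 0.05.

### Calibration and its limits

For a candidate whose observed count is itself drawn from the null process,
p should be approximately Uniform(0, 1). Two discreteness effects bound
what "approximately" can mean. First, the strict-exceedance p of a discrete
statistic is sub-uniform by up to the largest point mass of the count
distribution; for a typical (low-degree) node that distribution is almost
all mass at zero, so calibration is only meaningful for a candidate with a
spread-out count distribution. The calibration experiment therefore uses
the maximum-degree hub of a 300-node preferential-attachment network and a
seed size of 30, where the hub's count ranges over ~200 values with point
masses ≈ 0.02. Second, with 200 trials the Kolmogorov–Smirnov distance of
even perfectly uniform draws has a 95th percentile near 0.096, so observed
KS values of 0.05–0.09 are sampling noise around a well-calibrated test.

## Evaluation statistics

Two hypergeometric tail conventions are used on purpose. The overlap test
between a candidate set (size n, overlap k) and a reference list (size K,
default 742) on an N-gene background (default 20000) uses the strictly
greater tail P(X > k); this convention reproduces the published overlap
p-values this method was validated against to their printed precision.
Per-term GO enrichment inside functional profiles uses the at-least tail
P(X ≥ k), because profiles take −log10 of the p-value and a strict tail
would be zero (−log10 = ∞) for any term fully contained in the set. Both
are scipy hypergeometric survival functions, stable over these parameter
ranges; profile values are capped at 300 (−log10 of the smallest normal
double is ≈ 307.65).

The comparison of two candidate sets' reference overlaps is a two-sided
Fisher exact test (minimum-likelihood convention). The 2×2 cells are laid
out exactly as overlap tables print them — per row (overlap, set size),
i.e. ((k1, n1), (k2, n2)) — not (overlap, non-overlap). This is the
convention under which the published comparison p-values (3.858e-3, 0.186)
are reproduced exactly; with (overlap, non-overlap) cells they are not
(1.558e-3, 0.173). The general-purpose `fisher_exact_2x2` takes arbitrary
cells; the convention lives only in the `compare_candidate_overlap` helper.

Functional similarity between two gene sets is the sample Pearson
correlation of their profiles over a shared term universe (default: every
term annotating at least one background gene). Zero-variance profiles are
an error, not a NaN.

## Synthetic data: what it emulates and what it does not

The generator produces the full input bundle. The background network is
preferential attachment (Barabási–Albert, default 500 nodes, 3 attachments
per node) because interactome degree distributions are heavy-tailed; an
Erdős–Rényi alternative is available for null-calibration work. Edge scores
are Uniform{150..999} — STRING's practical range above its common 150
floor. Planted "connectors" are wired to ⌈attach_fraction · n_seeds⌉
distinct seeds at score 999 (cost 1), which routes attached seed pairs
through them at cost 2; defaults are 20 seeds, 3 connectors, attachment
fraction 0.5.

Two generator choices keep the planted ground truth identifiable and are
part of the generator's design rather than tunable dials:

* Seeds and connectors are drawn from the low-degree periphery (bottom 0.2
  of the degree distribution — in a preferential-attachment graph, the
  minimum-degree shell). Disease genes are mostly non-hub, and a planted
  connector that coincided with a well-connected node would carry heavy
  shortest-path traffic under *any* seed set: for such a node the
  permutation null is true, and no seed-specific signal exists to recover.
* When the spoke budget allows (attach_fraction · n_connectors ≥ 1 per
  seed), every seed receives at least one spoke before remaining spokes are
  placed at random. An uncovered seed reaches the others through whatever
  background node is its cheapest exit, making that "gateway" node — not a
  connector — the seed-specific intermediate, i.e. a structural false
  positive of the scenario rather than of the method.

What the synthetic data does *not* emulate: STRING's score distribution
(strongly non-uniform), evidence-channel structure, network motifs beyond
degree heavy-tails, correlated annotations along the GO hierarchy, or
biologically meaningful gene identities. Passing the recovery tests
demonstrates that the pipeline detects planted seed-specific intermediacy
against a realistic-degree background — not that it would recover any
particular gene set on real interactome data.

Annotations assign each gene a fixed number of random background terms
(default 3 of 50) and give each designated enriched set a dedicated block
of 5 terms at assignment probability 0.9. Reference lists have exactly
controlled size and overlap. Every generator is a pure function of its
parameters and seed; scenarios regenerate byte-identically.

## Problem sizes used in the shipped experiments

The shipped tests and the acceptance script run: exhaustive-oracle
comparison on 200 random graphs of ≤ 8 nodes (all simple paths enumerated);
null calibration with 200 trials of 200 permutations on a 300-node network;
planted recovery over 20 scenario seeds at the default settings with 500
permutations (the selection rule's 2000-permutation default is used for
real analyses; 500 gives p-granularity 0.002, ample for an α = 0.05 call);
and the profile-similarity contrast over 20 replicates. Recovery across
scenario batches measures ≈ 0.92–0.97 of planted connectors at p < 0.05
with no false positives among non-planted path genes; both rates are
stochastic and vary a few percent with the seed.

## Known limitations

* The statistic counts one path per pair; genes lying only on co-optimal
  alternatives that lose the lexicographic tie-break receive no credit.
* Strict-exceedance p-values are conservative for candidates with heavy
  point masses and anti-conservative never; but *conditioning on being a
  path gene* inflates the apparent significance of the candidate pool as a
  whole — the per-gene p-value is calibrated, the screening step is not.
* The permutation null redraws seeds from the whole network; it does not
  preserve degree structure of the seed set (degree-preserving nulls are
  out of scope).
* With a one-to-many gene↔protein map, counts are tabulated per protein;
  collapsing to gene symbols takes the maximum count over a gene's
  proteins, which can double-count paralogous proteins on the same path.
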