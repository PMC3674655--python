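"""Exact gene-set statistics: hypergeometric overlap and Fisher's exact test.

Two tail conventions are deliberately distinct:

* The overlap test against a reference gene list uses the strictly-greater
  upper tail P(X > k). With a 20000-gene background and a 742-gene cancer
  reference this convention reproduces published overlap p-values to their
  printed precision.
* Per-term enrichment (used for functional profiles) uses the conventional
  at-least tail P(X >= k), so that a term fully contained in a gene set has
  a finite -log10 value.

Both are thin, validated wrappers over scipy's hypergeometric survival
function, which computes the tail stably for these parameter ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "OverlapTest",
    "hypergeom_overlap_pvalue",
    "term_enrichment_pvalue",
    "fisher_exact_2x2",
    "compare_candidate_overlap",
    "overlap_test",
]

DEFAULT_BACKGROUND = 20000  # protein-coding genes assumed in the genome
DEFAULT_REFERENCE_SIZE = 742


def _check_overlap_args(n: int, k: int, K: int, N: int) -> None:
    if N <= 0:
        raise ValueError("background size N must be positive")
    if not (0 <= K <= N):
        raise ValueError(f"reference size K={K} outside [0, N={N}]")
    if not (0 <= n <= N):
        raise ValueError(f"set size n={n} outside [0, N={N}]")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")


def hypergeom_overlap_pvalue(
    n: int, k: int, K: int = DEFAULT_REFERENCE_SIZE, N: int = DEFAULT_BACKGROUND,
    tail: str = "greater",
) -> float:
    """P-value for the overlap k between a size-n set and a size-K reference
    drawn from an N-gene background.

    tail="greater" (default) is the strictly-greater tail P(X > k);
    tail="at_least" gives P(X >= k).
    """
    _check_overlap_args(n, k, K, N)
    if tail == "greater":
        return float(stats.hypergeom.sf(k, N, K, n))
    if tail == "at_least":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


def term_enrichment_pvalue(
    set_size: int, term_hits_in_set: int, term_size: int, background_size: int
) -> float:
    """At-least upper tail P(X >= k) for a term's hits inside a gene set."""
    _check_overlap_args(set_size, term_hits_in_set, term_size, background_size)
    return float(stats.hypergeom.sf(term_hits_in_set - 1, background_size, term_size, set_size))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Conditional on the margins, sums the hypergeometric point probabilities
    of every table no more probable than the observed one (the
    minimum-likelihood convention of R's fisher.test).
    """
    ((a, b), (c, d)) = table
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    if all(x == 0 for x in cells):
        raise ValueError("all-zero contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


@dataclass(frozen=True)
class OverlapTest:
    """Result of a reference-overlap hypergeometric test."""

    n: int
    k: int
    K: int
    N: int
    p_value: float


def overlap_test(
    gene_set, reference, N: int = DEFAULT_BACKGROUND, tail: str = "greater"
) -> OverlapTest:
    """Hypergeometric overlap between a gene set and a reference list."""
    s, r = set(gene_set), set(reference)
    k = len(s & r)
    res = hypergeom_overlap_pvalue(len(s), k, len(r), N, tail=tail)
    return OverlapTest(n=len(s), k=k, K=len(r), N=N, p_value=res)


def compare_candidate_overlap(n1: int, k1: int, n2: int, k2: int) -> float:
    """Two-sided Fisher comparison of the reference-overlap of two gene sets.

    The 2x2 cells are laid out exactly as overlap tables print them —
    (overlap, set size) per row: ((k1, n1), (k2, n2)). Note the second column
    is the set's total size, not its non-overlapping remainder; this is the
    convention the reproduced published comparisons use.
    """
    for name, v in (("n1", n1), ("k1", k1), ("n2", n2), ("k2", k2)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("overlap cannot exceed set size")
    return fisher_exact_2x2(((k1, n1), (k2, n2)))
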