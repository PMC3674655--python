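"""GO functional profiles and their Pearson similarity.

A gene set's functional profile is the vector of -log10 per-term enrichment
p-values over a fixed term universe (at-least hypergeometric tail against the
annotated background). Two gene sets are functionally similar when their
profiles correlate: sets enriched for the same terms spike in the same
coordinates. The similarity statistic is the sample Pearson correlation of
the two profile vectors over a shared term universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from .enrichment import term_enrichment_pvalue

__all__ = [
    "GOAnnotation",
    "FunctionalProfile",
    "build_profile",
    "profile_similarity",
]

# -log10 of the smallest positive normal double is ~307.65; profiles cap at
# 300 by default so downstream arithmetic never meets an infinity.
DEFAULT_CAP = 300.0


class GOAnnotation:
    """Gene -> GO-term annotation with its inverted term -> genes index.

    The background is the set of genes carrying at least one term. The two
    indices are maintained as mutual inverses.
    """

    def __init__(self, gene_to_terms: dict[str, Iterable[str]] | None = None):
        self._g2t: dict[str, set[str]] = {}
        self._t2g: dict[str, set[str]] = {}
        if gene_to_terms:
            for gene, terms in gene_to_terms.items():
                for term in terms:
                    self.annotate(gene, term)

    def annotate(self, gene: str, term: str) -> None:
        self._g2t.setdefault(gene, set()).add(term)
        self._t2g.setdefault(term, set()).add(gene)

    @property
    def background(self) -> frozenset[str]:
        return frozenset(self._g2t)

    def terms(self) -> list[str]:
        """All terms annotating at least one gene, sorted."""
        return sorted(self._t2g)

    def genes_for_term(self, term: str) -> frozenset[str]:
        return frozenset(self._t2g.get(term, ()))

    def terms_for_gene(self, gene: str) -> frozenset[str]:
        return frozenset(self._g2t.get(gene, ()))

    def __len__(self) -> int:
        return len(self._g2t)

    @classmethod
    def read(cls, source: str | TextIO, aspect: str | None = None) -> "GOAnnotation":
        """Read a gene/term table: two tab-separated columns (gene, term), or
        GAF-style rows where column 3 is the gene symbol and column 5 the GO
        term (1-based; detected by a 'GO:' prefix in that column). An
        optional third column may carry a GO aspect letter; ``aspect``
        restricts to it."""
        close = isinstance(source, str)
        handle = open(source, "rt") if close else source
        ann = cls()
        try:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "!")):
                    continue
                parts = line.split("\t")
                if len(parts) >= 5 and parts[4].startswith("GO:"):
                    gene, term = parts[2], parts[4]
                    row_aspect = parts[8] if len(parts) > 8 else None
                elif len(parts) >= 2:
                    gene, term = parts[0], parts[1]
                    row_aspect = parts[2] if len(parts) > 2 else None
                else:
                    continue
                if parts[0].lower() == "gene":
                    continue
                if aspect is not None and row_aspect is not None and row_aspect != aspect:
                    continue
                ann.annotate(gene, term)
        finally:
            if close:
                handle.close()
        return ann

    def write(self, handle: TextIO) -> None:
        handle.write("gene\tterm\n")
        for gene in sorted(self._g2t):
            for term in sorted(self._g2t[gene]):
                handle.write(f"{gene}\t{term}\n")


@dataclass(frozen=True)
class FunctionalProfile:
    term_universe: tuple[str, ...]
    values: np.ndarray  # -log10 enrichment p per term, >= 0

    def __post_init__(self) -> None:
        if len(self.term_universe) != len(self.values):
            raise ValueError("term universe and value vector lengths differ")

    def write(self, handle: TextIO) -> None:
        handle.write("term\tneg_log10_p\n")
        for t, v in zip(self.term_universe, self.values):
            handle.write(f"{t}\t{v:.6g}\n")


def build_profile(
    gene_set: Iterable[str],
    annotation: GOAnnotation,
    term_universe: Sequence[str] | None = None,
    cap: float = DEFAULT_CAP,
) -> FunctionalProfile:
    """Profile a gene set as -log10 at-least enrichment p per term.

    The effective set is the intersection with the annotated background; the
    term universe defaults to every term annotating at least one background
    gene, in sorted order.
    """
    background = annotation.background
    eff = set(gene_set) & background
    if not eff:
        raise ValueError("gene set has no member in the annotated background")
    universe = tuple(term_universe) if term_universe is not None else tuple(annotation.terms())
    if not universe:
        raise ValueError("empty term universe")
    n, N = len(eff), len(background)
    values = np.empty(len(universe))
    for i, term in enumerate(universe):
        genes_t = annotation.genes_for_term(term)
        k = len(eff & genes_t)
        if k == 0:
            values[i] = 0.0  # P(X >= 0) = 1
            continue
        p = term_enrichment_pvalue(n, k, len(genes_t), N)
        values[i] = cap if p <= 0 else min(cap, -np.log10(p))
    return FunctionalProfile(term_universe=universe, values=values)


def profile_similarity(p1: FunctionalProfile, p2: FunctionalProfile) -> float:
    """Sample Pearson correlation of two profiles over the same term universe."""
    if p1.term_universe != p2.term_universe:
        raise ValueError("profiles span different term universes")
    v1, v2 = np.asarray(p1.values, float), np.asarray(p2.values, float)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    return float(np.corrcoef(v1, v2)[0, 1])
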