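"""Gene-list overlap and over-representation analysis.

Overlap against reference risk-gene sets is purely set intersection.
Over-representation uses the one-tailed hypergeometric (Fisher exact) test:
for a query of s genes drawn from a universe of U, the probability that a
reference set of m genes shares at least k members with the query. Multiple
testing is corrected with q = p*N/r, where N is the number of sets actually
tested and r the rank of the p-value — the raw Benjamini-Hochberg formula
with no monotonicity post-processing; a capped-at-1 value is reported
alongside the raw one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import GeneSetCollection


@dataclass(frozen=True)
class OverlapResult:
    set_name: str
    overlap_genes: frozenset[str]
    k: int
    set_size: int


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_genes: frozenset[str]
    k: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    rank: int
    q_raw: float
    q: float            # capped at 1.0


def overlap(
    query_genes: Sequence[str],
    reference_sets: GeneSetCollection,
) -> list[OverlapResult]:
    """Intersection of the query list with each reference set; sets with
    zero overlap are retained with k = 0."""
    query = frozenset(g.upper() for g in query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    results = []
    for name, genes in reference_sets.items():
        shared = query & genes
        results.append(
            OverlapResult(
                set_name=name,
                overlap_genes=shared,
                k=len(shared),
                set_size=len(genes),
            )
        )
    return results


def hypergeom_pvalue(k: int, universe: int, set_size: int, query: int) -> float:
    """P(K >= k) for the overlap of a random query with a fixed set."""
    return float(stats.hypergeom.sf(k - 1, universe, set_size, query))


def fisher_enrichment(
    query_genes: Sequence[str],
    reference_sets: GeneSetCollection,
    universe: Sequence[str],
    min_overlap: int = 2,
    p_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Over-representation of each reference set in the query list.

    Sets overlapping the query by fewer than ``min_overlap`` genes are
    excluded before testing (they do not count toward N); results with
    p < ``p_cutoff`` are returned, ranked by p with q = p*N/r.
    """
    universe_set = frozenset(g.upper() for g in universe)
    query = frozenset(g.upper() for g in query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    if len(universe_set) < len(query):
        raise ValueError("universe smaller than query")
    if not query <= universe_set:
        raise ValueError(
            "query genes outside universe: "
            + ", ".join(sorted(query - universe_set)[:5])
        )

    tested = []
    for name, genes in reference_sets.items():
        genes = genes & universe_set
        shared = query & genes
        if len(shared) < min_overlap:
            continue
        p = hypergeom_pvalue(len(shared), len(universe_set), len(genes),
                             len(query))
        tested.append((name, shared, len(genes), p))

    n_tests = len(tested)
    order = np.argsort([t[3] for t in tested], kind="stable")
    results = []
    for rank, idx in enumerate(order, start=1):
        name, shared, m, p = tested[idx]
        if p >= p_cutoff:
            continue
        q_raw = p * n_tests / rank
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_genes=shared,
                k=len(shared),
                set_size=m,
                query_size=len(query),
                universe_size=len(universe_set),
                p=p,
                rank=rank,
                q_raw=q_raw,
                q=min(1.0, q_raw),
            )
        )
    return results
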