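"""Hypergeometric GO term enrichment for protein sets and interaction sets.

The protein-set test uses the classical four numbers: k proteins annotated
with the term inside the set, set size n, K annotated proteins in the
universe, universe size N; the p-value is the inclusive upper tail
P(X >= k).  The pair-based variant treats unordered protein pairs as the
sampling units: an interaction "carries" a term when both endpoints are
annotated with it, the universe becomes all C(N, 2) possible pairs and the
term's background count becomes C(K_t, 2).

Filtering follows the study's rules: raw p < 0.05, process-namespace
terms, and at least 3 annotated set members -- relaxed to 2 members (and
function terms admitted) for small protein clusters.  No multiple-testing
correction is applied by default; Benjamini-Hochberg is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_io import GOAnnotationSet, canonical_edge


@dataclass
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    k: int  # annotated in set
    n: int  # set size
    K: int  # annotated in universe
    N: int  # universe size
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must be in (0, 1]")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Inclusive upper-tail hypergeometric probability P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def protein_set_enrichment(
    protein_set: Iterable[str],
    annotations: GOAnnotationSet,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Per-term enrichment of a protein set against the annotation universe.

    Only terms annotating at least one set member are reported.
    """
    universe_set = set(universe) if universe is not None else set(annotations.universe)
    pset = set(protein_set)
    offenders = pset - universe_set
    if offenders:
        raise ValueError(
            f"set proteins outside the universe: {sorted(offenders)[:10]}"
        )
    N = len(universe_set)
    n = len(pset)
    term_counts_universe: dict[str, int] = {}
    term_counts_set: dict[str, int] = {}
    for protein, terms in annotations.protein_terms.items():
        if protein not in universe_set:
            continue
        for t in terms:
            term_counts_universe[t] = term_counts_universe.get(t, 0) + 1
            if protein in pset:
                term_counts_set[t] = term_counts_set.get(t, 0) + 1
    results = []
    for term, k in sorted(term_counts_set.items()):
        K = term_counts_universe[term]
        results.append(
            EnrichmentResult(
                term=term,
                name=annotations.term_name.get(term, ""),
                namespace=annotations.term_namespace[term],
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=hypergeom_upper_tail(k, n, K, N),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def pair_set_enrichment(
    interaction_set: Iterable[tuple[str, str]],
    annotations: GOAnnotationSet,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment over interaction pairs: a pair carries a term when both
    endpoints are annotated with it.

    k = interactions in the set carrying the term, n = interactions in the
    set, K = C(K_t, 2) annotated-annotated pairs in the proteome, N = C(N_p,
    2) possible pairs.  Terms annotating fewer than two universe proteins
    have K = 0 and are skipped.
    """
    universe_set = set(universe) if universe is not None else set(annotations.universe)
    edges = [canonical_edge(*e) for e in interaction_set]
    for a, b in edges:
        if a not in universe_set or b not in universe_set:
            raise ValueError(f"interaction ({a}, {b}) outside the universe")
    n = len(edges)
    N_p = len(universe_set)
    N = N_p * (N_p - 1) // 2
    term_universe_proteins: dict[str, int] = {}
    for protein, terms in annotations.protein_terms.items():
        if protein not in universe_set:
            continue
        for t in terms:
            term_universe_proteins[t] = term_universe_proteins.get(t, 0) + 1
    shared_counts: dict[str, int] = {}
    for a, b in edges:
        common = annotations.protein_terms.get(a, set()) & annotations.protein_terms.get(
            b, set()
        )
        for t in common:
            shared_counts[t] = shared_counts.get(t, 0) + 1
    results = []
    for term, k in sorted(shared_counts.items()):
        K_t = term_universe_proteins.get(term, 0)
        K = K_t * (K_t - 1) // 2
        if K == 0:
            continue
        results.append(
            EnrichmentResult(
                term=term,
                name=annotations.term_name.get(term, ""),
                namespace=annotations.term_namespace[term],
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=hypergeom_upper_tail(k, n, K, N),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def filter_terms(
    results: Sequence[EnrichmentResult], mode: str = "standard"
) -> list[EnrichmentResult]:
    """Apply the standard filtering rules.

    standard: process terms with p < 0.05 and k >= 3.
    cluster:  p < 0.05 and k >= 2; process and function terms admitted.
    """
    if mode == "standard":
        return [
            r
            for r in results
            if r.p_value < 0.05 and r.namespace == "process" and r.k >= 3
        ]
    if mode == "cluster":
        return [
            r
            for r in results
            if r.p_value < 0.05
            and r.namespace in ("process", "function")
            and r.k >= 2
        ]
    raise ValueError(f"unknown mode {mode!r}")


def benjamini_hochberg(results: Sequence[EnrichmentResult]) -> list[float]:
    """BH-adjusted q-values in the order of ``results`` (optional, off by default)."""
    p = np.array([r.p_value for r in results])
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q.tolist()
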