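"""Parsimony quantification of PPI change across the five-species phylogeny.

For every interaction present in at least one species, the minimum number of
presence/absence state changes (a_ij) on the tree is inferred by parsimony;
a protein's gamma is the sum of a_ij over its interaction profiles.
Real-data gamma values are compared against a per-protein null distribution
of gamma from simulated proteomes: strictly below every null replicate means
conserved, strictly above every replicate means rapidly evolving.

Two parsimony modes are provided.  ``fitch`` is standard small parsimony
(free root); ``ancestral-present`` fixes the root state to "interaction
present", reflecting that candidate interactions derive from an
*S. cerevisiae* database, and caps the change count at three
per pattern on the rooted ladder topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import Phylogeny, canonical_edge

#: Rooted ladder topology of the sensu stricto clade used for parsimony.
SENSU_STRICTO_NEWICK = "(Sbay,(Skud,(Smik,(Spar,Scer))));"

MODES = ("fitch", "ancestral-present")


@dataclass
class PresenceProfile:
    """Presence/absence of one interaction across the species set."""

    pair: tuple[str, str]
    presence: dict[str, bool]
    changes: int | None = None

    def __post_init__(self) -> None:
        self.pair = canonical_edge(*self.pair)
        if not any(self.presence.values()):
            raise ValueError("all-absent profiles are never constructed")


@dataclass
class GammaRecord:
    protein: str
    gamma: int
    degree: int


@dataclass
class GammaSummary:
    median: float
    mean: float
    variance: float


@dataclass
class ClassificationResult:
    protein: str
    label: str  # conserved | rapid | neither


def build_presence_profiles(
    interactomes: Mapping[str, Iterable[tuple[str, str]]],
) -> list[PresenceProfile]:
    """One profile per edge in the union of the per-species interactomes."""
    canon = {
        sp: {canonical_edge(*e) for e in edges} for sp, edges in interactomes.items()
    }
    union = set().union(*canon.values()) if canon else set()
    return [
        PresenceProfile(
            pair=edge, presence={sp: edge in canon[sp] for sp in canon}
        )
        for edge in sorted(union)
    ]


def _sankoff_min_changes(
    tree: Phylogeny, leaf_states: Mapping[str, int], root_state: int | None
) -> int:
    """Minimum state changes for a binary character by dynamic programming."""
    INF = 10**9
    cost: dict[str, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = leaf_states[node.label]
            cost[node.label] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            c = [0, 0]
            for child in node.children:
                cc = cost[child.label]
                for s in (0, 1):
                    c[s] += min(cc[0] + (s != 0), cc[1] + (s != 1))
            cost[node.label] = c
    root_cost = cost[tree.root.label]
    if root_state is None:
        return min(root_cost)
    return root_cost[root_state]


def count_changes(
    profile: PresenceProfile, tree: Phylogeny, mode: str = "ancestral-present"
) -> int:
    """a_ij: minimum number of gains/losses explaining a presence pattern."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    leaves = set(tree.leaf_labels())
    if set(profile.presence) != leaves:
        raise ValueError(
            f"profile species {sorted(profile.presence)} do not match tree "
            f"leaves {sorted(leaves)}"
        )
    leaf_states = {sp: int(v) for sp, v in profile.presence.items()}
    root_state = 1 if mode == "ancestral-present" else None
    return _sankoff_min_changes(tree, leaf_states, root_state)


def compute_gamma(
    profiles: Sequence[PresenceProfile],
    tree: Phylogeny,
    mode: str = "ancestral-present",
    reference_species: str = "Scer",
) -> list[GammaRecord]:
    """Per-protein gamma (sum of a_ij over its profiles) and reference degree.

    Degree counts the protein's partners in the reference (S. cerevisiae)
    interactome; gamma sums over every profile the protein participates in,
    present in the reference or not.
    """
    pattern_cache: dict[tuple, int] = {}
    gamma: dict[str, int] = {}
    degree: dict[str, int] = {}
    species_order = sorted(next(iter(profiles)).presence) if profiles else []
    for profile in profiles:
        key = tuple(profile.presence[sp] for sp in species_order)
        if key not in pattern_cache:
            pattern_cache[key] = count_changes(profile, tree, mode)
        a_ij = pattern_cache[key]
        profile.changes = a_ij
        for prot in profile.pair:
            gamma[prot] = gamma.get(prot, 0) + a_ij
            if profile.presence.get(reference_species, False):
                degree[prot] = degree.get(prot, 0) + 1
            else:
                degree.setdefault(prot, 0)
    return [
        GammaRecord(protein=p, gamma=gamma[p], degree=degree[p])
        for p in sorted(gamma)
    ]


def summarize_gamma(records: Sequence[GammaRecord] | Sequence[float]) -> GammaSummary:
    """Median, mean and sample variance (n-1 denominator) of gamma values."""
    if len(records) == 0:
        raise ValueError("no gamma records")
    values = [
        float(r.gamma) if isinstance(r, GammaRecord) else float(r) for r in records
    ]
    arr = np.asarray(values)
    var = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    return GammaSummary(median=float(median(values)), mean=float(arr.mean()), variance=var)


def classify_proteins(
    real: Sequence[GammaRecord],
    null: Mapping[str, Sequence[float]],
) -> list[ClassificationResult]:
    """Conserved / rapid / neither against the per-protein null distribution.

    Strict inequalities: a protein is conserved only when its real gamma is
    below *every* null replicate, rapid only when above every replicate;
    equality with any null value yields "neither".
    """
    lengths = {len(v) for v in null.values()}
    if len(lengths) > 1:
        raise ValueError(f"null vectors have inconsistent lengths {sorted(lengths)}")
    out = []
    for rec in real:
        if rec.protein not in null:
            raise ValueError(f"missing null distribution for protein {rec.protein!r}")
        vals = np.asarray(null[rec.protein], dtype=float)
        if rec.gamma < vals.min():
            label = "conserved"
        elif rec.gamma > vals.max():
            label = "rapid"
        else:
            label = "neither"
        out.append(ClassificationResult(protein=rec.protein, label=label))
    return out


def species_specific_interactions(
    real_edges: Iterable[tuple[str, str]],
    sim_edge_sets: Sequence[Iterable[tuple[str, str]]],
) -> set[tuple[str, str]]:
    """Edges present in the real interactome but in no simulated replicate."""
    real = {canonical_edge(*e) for e in real_edges}
    sim_union: set[tuple[str, str]] = set()
    for edges in sim_edge_sets:
        sim_union |= {canonical_edge(*e) for e in edges}
    return real - sim_union


def conserved_core(
    per_species_specific: Mapping[str, Iterable[tuple[str, str]]] | Sequence[Iterable[tuple[str, str]]],
    reference_edges: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Intersection of the species-specific sets with the reference interactome."""
    if isinstance(per_species_specific, Mapping):
        sets = list(per_species_specific.values())
    else:
        sets = list(per_species_specific)
    result = {canonical_edge(*e) for e in reference_edges}
    for s in sets:
        result &= {canonical_edge(*e) for e in s}
    return result


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided normal-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def fisher_overlap(size_a: int, size_b: int, overlap: int, universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for the overlap of two sets.

    Hypergeometric upper tail P(X >= overlap) with population ``universe``,
    ``size_a`` successes and ``size_b`` draws.
    """
    if not (0 <= overlap <= min(size_a, size_b) <= universe):
        raise ValueError("inconsistent counts")
    if max(size_a, size_b) > universe:
        raise ValueError("set larger than universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
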