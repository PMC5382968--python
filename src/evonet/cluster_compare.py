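"""Cluster similarity scoring and uniqueness against simulated interactomes.

Two clusters' similarity is the size of their intersection divided by the
size of the larger cluster, which is always in [0, 1].  A real-interactome
cluster is "unique" when no cluster from any simulated replicate matches it
at or above the match threshold (0.7 by default, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError(
                f"cluster {self.cluster_id!r} must have at least 2 members"
            )


def clusters_from_membership(
    membership: Mapping[str, Iterable[str]], source: str = ""
) -> list[Cluster]:
    """Build Cluster objects from a cluster_id -> members mapping."""
    return [
        Cluster(cluster_id=cid, members=frozenset(members), source=source)
        for cid, members in sorted(membership.items())
    ]


def cluster_similarity(a: Cluster, b: Cluster) -> float:
    """|a n b| / max(|a|, |b|); symmetric, in [0, 1]."""
    if not a.members or not b.members:
        raise ValueError("clusters must be non-empty")
    return len(a.members & b.members) / max(len(a.members), len(b.members))


def unique_clusters(
    real_clusters: Sequence[Cluster],
    sim_cluster_sets: Sequence[Sequence[Cluster]],
    match_threshold: float = 0.7,
) -> list[Cluster]:
    """Real clusters with no match (similarity >= threshold) in any replicate."""
    if not 0 < match_threshold <= 1:
        raise ValueError("match threshold must be in (0, 1]")
    if len(sim_cluster_sets) == 0:
        raise ValueError("uniqueness is undefined without simulated cluster sets")
    out = []
    for rc in real_clusters:
        matched = any(
            cluster_similarity(rc, sc) >= match_threshold
            for sim_set in sim_cluster_sets
            for sc in sim_set
        )
        if not matched:
            out.append(rc)
    return out
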