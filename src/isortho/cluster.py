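"""Anchor-pair sub-clustering of an orthologue group's isoforms.

The iteration mirrors the seed-and-expand scheme familiar from
InParanoid-style orthologue detection, applied within one group:

1. among unassigned isoforms, the best-scoring *cross-species* pair
   becomes the anchors of a new sub-cluster;
2. every unassigned same-species isoform whose similarity to its
   species' anchor strictly exceeds the anchor-pair score joins the
   cluster;
3. repeat while both species still have unassigned isoforms;
4. leftovers become singleton sub-clusters.

"Strictly exceeds" matters: an isoform tied with the anchor score is
not absorbed (``expand_on_tie`` switches to ≥).  Ties for the best
anchor pair are broken on the lexicographically smallest sorted id
pair, so clustering is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import OrthologueGroup
from .similarity import SimilarityMatrix


@dataclass
class SubCluster:
    """One transcript-level sub-cluster.

    Anchored clusters carry exactly one anchor per species and the
    anchor-pair similarity; singletons carry neither.
    members is a list of (isoform_id, species) pairs.
    """

    cluster_index: int
    anchor_a: str | None
    anchor_b: str | None
    anchor_score: float | None
    members: list[tuple[str, str]]

    @property
    def is_singleton(self) -> bool:
        return self.anchor_a is None

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]


@dataclass
class GroupClustering:
    """Ordered sub-clusters partitioning one orthologue group."""

    group_id: str
    clusters: list[SubCluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, isoform_id: str) -> int:
        for cl in self.clusters:
            if isoform_id in cl.member_ids:
                return cl.cluster_index
        raise KeyError(isoform_id)

    def as_partition(self) -> dict[str, int]:
        return {
            m: cl.cluster_index for cl in self.clusters for m in cl.member_ids
        }


def subcluster_group(
    group: OrthologueGroup,
    sim: SimilarityMatrix,
    expand_on_tie: bool = False,
) -> GroupClustering:
    """Partition a group's isoforms by the anchor-pair iteration."""
    species_of = {iso.isoform_id: iso.species for iso in group.isoforms}
    unassigned_a = sorted(
        iso.isoform_id for iso in group.members_of(group.species_a)
    )
    unassigned_b = sorted(
        iso.isoform_id for iso in group.members_of(group.species_b)
    )

    clusters: list[SubCluster] = []
    index = 0
    while unassigned_a and unassigned_b:
        # Best cross-species pair; ties -> lexicographically smallest
        # sorted (id, id) pair.
        best_pair = None
        best_score = -1.0
        for a in unassigned_a:
            for b in unassigned_b:
                s = sim.sim(a, b)
                key = tuple(sorted((a, b)))
                if s > best_score or (s == best_score and key < best_pair[0]):
                    best_pair = (key, a, b)
                    best_score = s
        _, anchor_a, anchor_b = best_pair

        members = [(anchor_a, species_of[anchor_a]), (anchor_b, species_of[anchor_b])]
        for pool, anchor in ((unassigned_a, anchor_a), (unassigned_b, anchor_b)):
            for m in pool:
                if m == anchor:
                    continue
                s = sim.sim(m, anchor)
                if s > best_score or (expand_on_tie and s == best_score):
                    members.append((m, species_of[m]))

        index += 1
        clusters.append(
            SubCluster(
                cluster_index=index,
                anchor_a=anchor_a,
                anchor_b=anchor_b,
                anchor_score=best_score,
                members=members,
            )
        )
        taken = {m for m, _ in members}
        unassigned_a = [m for m in unassigned_a if m not in taken]
        unassigned_b = [m for m in unassigned_b if m not in taken]

    for m in sorted(unassigned_a + unassigned_b):
        index += 1
        clusters.append(
            SubCluster(
                cluster_index=index,
                anchor_a=None,
                anchor_b=None,
                anchor_score=None,
                members=[(m, species_of[m])],
            )
        )
    return GroupClustering(group_id=group.group_id, clusters=clusters)


def count_subclusters(clustering: GroupClustering) -> int:
    """Number of sub-clusters, singletons included."""
    return clustering.n_clusters
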