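"""Functional verification of sub-clusters via signature vectors.

Each isoform of a group gets a binary vector over the union of
functional signatures (InterPro-style accessions) hitting *any* isoform
of that group: bit k is 1 iff the isoform matched signature k.  The
functional difference of two isoforms, diff_func, is the Hamming
distance between their vectors — the number of signatures at which they
differ.

Per-group summaries average diff_func over pairs sharing a sub-cluster
(intra) and pairs in different sub-clusters (inter); groups whose
isoforms all carry identical vectors can be flagged excluded, matching
the usual practice of analysing only groups where differences exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable

import numpy as np

from .cluster import GroupClustering
from .io import OrthologueGroup, SignatureAssignment


@dataclass
class SignatureVector:
    """Binary signature presence vector over a group-wide universe."""

    isoform_id: str
    universe: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.universe),):
            raise ValueError("bit vector length must match universe size")


@dataclass
class GroupDiffSummary:
    """Intra- vs inter-cluster mean of a pairwise difference measure.

    A mean is None exactly when the corresponding pair count is 0.
    ``excluded`` marks groups where every pairwise difference was 0 and
    the skip-if-all-equal filter was requested.
    """

    group_id: str
    measure: str
    intra_mean: float | None
    inter_mean: float | None
    n_intra_pairs: int
    n_inter_pairs: int
    excluded: bool = False


def build_signature_vectors(
    group: OrthologueGroup, assignments: Iterable[SignatureAssignment]
) -> list[SignatureVector]:
    """Signature vectors for every isoform of a group.

    The universe is the sorted union of signatures assigned to any group
    isoform; isoforms with no assignments get all-zero vectors.
    """
    member_ids = set(group.isoform_ids)
    per_iso: dict[str, set[str]] = {i: set() for i in group.isoform_ids}
    universe_set: set[str] = set()
    for a in assignments:
        if a.isoform_id in member_ids:
            per_iso[a.isoform_id].add(a.signature_accession)
            universe_set.add(a.signature_accession)
    universe = tuple(sorted(universe_set))
    return [
        SignatureVector(
            isoform_id=iso_id,
            universe=universe,
            bits=np.array([1 if s in per_iso[iso_id] else 0 for s in universe], dtype=np.uint8),
        )
        for iso_id in group.isoform_ids
    ]


def diff_func(v1: SignatureVector, v2: SignatureVector) -> int:
    """Hamming distance between two signature vectors."""
    if v1.universe != v2.universe:
        raise ValueError("signature vectors built over different universes")
    return int(np.count_nonzero(v1.bits != v2.bits))


def group_diff_summary(
    clustering: GroupClustering,
    pair_diff: Callable[[str, str], float],
    measure: str,
    skip_if_all_equal: bool = False,
) -> GroupDiffSummary:
    """Average a pairwise difference within and between sub-clusters.

    ``pair_diff(id1, id2)`` must be defined for every isoform pair of
    the group.  Undefined means (no pairs on that side) are reported as
    None, never as 0.
    """
    partition = clustering.as_partition()
    ids = sorted(partition)
    intra: list[float] = []
    inter: list[float] = []
    for id1, id2 in combinations(ids, 2):
        d = pair_diff(id1, id2)
        (intra if partition[id1] == partition[id2] else inter).append(d)
    excluded = bool(
        skip_if_all_equal and all(d == 0 for d in intra + inter)
    )
    return GroupDiffSummary(
        group_id=clustering.group_id,
        measure=measure,
        intra_mean=float(np.mean(intra)) if intra else None,
        inter_mean=float(np.mean(inter)) if inter else None,
        n_intra_pairs=len(intra),
        n_inter_pairs=len(inter),
        excluded=excluded,
    )
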