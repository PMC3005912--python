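"""Intrinsic-disorder verification of sub-clusters.

Per-residue disorder predictions (e.g. PONDR-family scores) are turned
into disordered regions by thresholding (default 0.5, the predictors'
usual convention), then cleaned with two rules applied per isoform:

* regions separated by fewer than ``merge_gap`` ordered residues
  (default 3, i.e. 0–2 residues between them) are combined, and
* regions shorter than ``min_len`` residues (default 10) are ignored.

By default merging precedes the length filter, so two nearby short
fragments that plausibly represent one region survive as their merged
whole; the opposite order is available via ``order='filter_then_merge'``.

The structural difference of two isoforms, diff_dis, is the absolute
difference in their disordered-region counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import DisorderAnnotation, FormatError


@dataclass
class DisorderProfile:
    """Filtered disordered regions of one isoform.

    regions are 1-based inclusive residue intervals, sorted and
    non-overlapping.
    """

    isoform_id: str
    regions: list[tuple[int, int]]
    protein_len: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_len(self) -> int:
        return sum(e - s + 1 for s, e in self.regions)


def scores_to_regions(
    scores: Sequence[float], threshold: float = 0.5
) -> list[tuple[int, int]]:
    """Maximal runs of residues with score >= threshold, 1-based inclusive."""
    regions: list[tuple[int, int]] = []
    start = None
    for pos, score in enumerate(scores, start=1):
        if score >= threshold:
            if start is None:
                start = pos
        elif start is not None:
            regions.append((start, pos - 1))
            start = None
    if start is not None:
        regions.append((start, len(scores)))
    return regions


def _merge(regions: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in regions:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        else:
            merged.append((start, end))
    return merged


def filter_regions(
    raw: Sequence[tuple[int, int]],
    protein_len: int,
    isoform_id: str = "",
    min_len: int = 10,
    merge_gap: int = 3,
    order: str = "merge_then_filter",
) -> DisorderProfile:
    """Clean raw disorder intervals into a DisorderProfile.

    Input intervals must be sorted and non-overlapping.  With the
    default order, intervals separated by < merge_gap residues are
    merged first and merged intervals shorter than min_len dropped
    second.
    """
    if order not in ("merge_then_filter", "filter_then_merge"):
        raise ValueError(f"unknown order {order!r}")
    regions = list(raw)
    for i in range(1, len(regions)):
        if regions[i][0] <= regions[i - 1][1]:
            raise FormatError(
                f"isoform {isoform_id!r}: intervals unsorted or overlapping"
            )
    for start, end in regions:
        if start < 1 or (protein_len and end > protein_len):
            raise FormatError(
                f"isoform {isoform_id!r}: interval ({start}, {end}) outside "
                f"[1, {protein_len}]"
            )

    def length_filter(rs):
        return [r for r in rs if r[1] - r[0] + 1 >= min_len]

    if order == "merge_then_filter":
        regions = length_filter(_merge(regions, merge_gap))
    else:
        regions = _merge(length_filter(regions), merge_gap)
    return DisorderProfile(
        isoform_id=isoform_id, regions=regions, protein_len=protein_len
    )


def profile_from_annotation(
    ann: DisorderAnnotation,
    protein_len: int | None = None,
    threshold: float = 0.5,
    min_len: int = 10,
    merge_gap: int = 3,
    order: str = "merge_then_filter",
) -> DisorderProfile:
    """Build a filtered profile from a raw annotation (either dialect).

    For the intervals dialect a protein length may be unknown; it then
    defaults to the largest interval end (sufficient for diff_dis,
    which only uses region counts).
    """
    if ann.scores is not None:
        raw = scores_to_regions(ann.scores, threshold)
        plen = len(ann.scores)
    else:
        raw = ann.regions
        plen = protein_len or (max((e for _, e in raw), default=0))
    return filter_regions(
        raw,
        protein_len=plen,
        isoform_id=ann.isoform_id,
        min_len=min_len,
        merge_gap=merge_gap,
        order=order,
    )


def diff_dis(p1: DisorderProfile, p2: DisorderProfile) -> int:
    """Absolute difference in disordered-region counts."""
    return abs(p1.n_regions - p2.n_regions)


def disorder_fraction(p: DisorderProfile) -> float:
    """Fraction of residues inside disordered regions."""
    if p.protein_len <= 0:
        raise ValueError("protein_len must be positive")
    return p.total_len / p.protein_len
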