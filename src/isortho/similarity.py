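"""Pairwise isoform similarity projected from the group alignment.

For two isoforms P1, P2 the score is

    Sim(P1, P2) = (# identity-or-substitution columns) / (aligned length incl. gaps)

computed on the *pairwise projection* of the group MSA: the two rows
restricted to columns where at least one of them carries a residue.
Columns gapped in both rows belong to exons absent from both isoforms
and are excluded — this is what makes two isoforms with the same exon
structure score exactly 1 even when other group members carry extra
exons.

Identities and substitutions count alike (no substitution matrix enters
the score): a residue paired with a residue is evidence the two isoforms
share that exon, whatever the residues are.  Because heuristic multiple
aligners can scatter a few spuriously paired columns, maximal
residue–residue runs ("common regions") shorter than ``d`` residues
(default 2) are dropped from the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .io import GAP
from .align import MultipleAlignment


@dataclass(frozen=True)
class PairwiseProjection:
    """Two MSA rows with their mutual all-gap columns removed."""

    id1: str
    id2: str
    row1: str
    row2: str

    @property
    def length(self) -> int:
        return len(self.row1)


@dataclass(frozen=True)
class CommonRegion:
    """A maximal run of columns where both rows carry residues.

    Half-open 0-based column interval of the projection.
    """

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SimilarityMatrix:
    """Symmetric isoform-pair similarity scores in [0, 1]."""

    ids: list[str]
    _sim: dict[frozenset, float]

    def sim(self, id1: str, id2: str) -> float:
        if id1 == id2:
            if id1 not in self.ids:
                raise KeyError(id1)
            return 1.0
        key = frozenset((id1, id2))
        if key not in self._sim:
            raise KeyError((id1, id2))
        return self._sim[key]

    def pairs(self):
        for id1, id2 in combinations(self.ids, 2):
            yield id1, id2, self.sim(id1, id2)


def project_pair(msa: MultipleAlignment, id1: str, id2: str) -> PairwiseProjection:
    """Extract two rows from the MSA, dropping double-gap columns."""
    r1, r2 = msa.row(id1), msa.row(id2)
    kept = [(a, b) for a, b in zip(r1, r2) if not (a == GAP and b == GAP)]
    return PairwiseProjection(
        id1=id1,
        id2=id2,
        row1="".join(a for a, _ in kept),
        row2="".join(b for _, b in kept),
    )


def common_regions(proj: PairwiseProjection) -> list[CommonRegion]:
    """Maximal runs of residue–residue columns, left to right."""
    regions: list[CommonRegion] = []
    start = None
    for i, (a, b) in enumerate(zip(proj.row1, proj.row2)):
        both = a != GAP and b != GAP
        if both and start is None:
            start = i
        elif not both and start is not None:
            regions.append(CommonRegion(start, i))
            start = None
    if start is not None:
        regions.append(CommonRegion(start, proj.length))
    return regions


def similarity(
    proj: PairwiseProjection,
    min_region_len: int = 2,
    d_filter_mode: str = "numerator",
) -> float:
    """Similarity score of a projected pair.

    The numerator counts columns inside common regions of length at
    least ``min_region_len`` (the d-filter).  With the default
    ``d_filter_mode='numerator'`` the denominator is the full projection
    length including gap columns; with ``'both'`` the columns of
    sub-threshold regions are also removed from the denominator.
    """
    if proj.length == 0:
        raise ValueError("zero-length projection")
    if d_filter_mode not in ("numerator", "both"):
        raise ValueError(f"unknown d_filter_mode {d_filter_mode!r}")
    regions = common_regions(proj)
    kept = sum(len(r) for r in regions if len(r) >= min_region_len)
    denom = proj.length
    if d_filter_mode == "both":
        denom -= sum(len(r) for r in regions if len(r) < min_region_len)
    if denom == 0:
        return 0.0
    return kept / denom


def similarity_matrix(
    msa: MultipleAlignment,
    min_region_len: int = 2,
    d_filter_mode: str = "numerator",
) -> SimilarityMatrix:
    """All unordered pairwise similarity scores from a group MSA."""
    sims: dict[frozenset, float] = {}
    for id1, id2 in combinations(msa.ids, 2):
        proj = project_pair(msa, id1, id2)
        sims[frozenset((id1, id2))] = similarity(proj, min_region_len, d_filter_mode)
    return SimilarityMatrix(ids=list(msa.ids), _sim=sims)


def write_similarity_tsv(group_id: str, sim: SimilarityMatrix, fh) -> None:
    """Append one group's pairwise scores to an open similarity TSV."""
    for id1, id2, s in sim.pairs():
        a, b = sorted((id1, id2))
        fh.write(f"{group_id}\t{a}\t{b}\t{s:.6f}\n")
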