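"""Global alignment of isoform sets.

Isoforms of one gene are near-identical over shared exons and differ by
the presence or absence of whole exons, so a *global* alignment places
homologous exons on top of each other and turns skipped exons into gap
blocks.  (A local aligner would happily report a perfect hit on the
shared exons and hide the difference — which is exactly why the
similarity score downstream is computed on a global multiple alignment.)

Two routes produce the group alignment:

* :func:`align_group` — a built-in deterministic progressive aligner:
  affine-gap Needleman–Wunsch (Gotoh) pairwise distances, a UPGMA guide
  tree, and profile–profile merging leaf-to-root.
* :func:`ingest_alignment` — validation and ingestion of a precomputed
  alignment (e.g. genuine MUSCLE output) from aligned FASTA.

The pairwise traceback resolves score ties in the fixed order
diagonal > up > left, so alignments are reproducible across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import GAP, FormatError, OrthologueGroup, read_fasta

# Residue alphabet used internally: 20 amino acids, ambiguity codes,
# selenocysteine, and the gap symbol (always last).
ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZXU" + GAP
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_NGAP = len(ALPHABET) - 1  # index of the gap symbol


def _blosum62_matrix() -> np.ndarray:
    """Dense score matrix over ALPHABET from BLOSUM62.

    Symbols absent from BLOSUM62 (U) and the gap symbol score 0 against
    everything; a gap inside an existing profile column therefore
    contributes nothing to a column-pair score.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            if a in blosum.alphabet and b in blosum.alphabet:
                m[i, j] = blosum[a][b]
    return m


_BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters.

    gap_open is the cost of the first column of a gap, gap_extend of
    each further column; both are ≤ 0 with gap_open ≤ gap_extend.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.matrix != "BLOSUM62":
            raise ValueError(f"unknown substitution matrix {self.matrix!r}")

    @property
    def score_matrix(self) -> np.ndarray:
        return _BLOSUM62


@dataclass
class MultipleAlignment:
    """An MSA: ordered (isoform_id, aligned string) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise FormatError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, isoform_id: str) -> str:
        for rid, s in self.rows:
            if rid == isoform_id:
                return s
        raise KeyError(isoform_id)

    def drop_all_gap_columns(self) -> "MultipleAlignment":
        keep = [
            i
            for i in range(self.length)
            if any(s[i] != GAP for _, s in self.rows)
        ]
        return MultipleAlignment(
            [(rid, "".join(s[i] for i in keep)) for rid, s in self.rows]
        )


def _validate_sequence(seq: str) -> None:
    bad = set(seq) - set(ALPHABET[:-1])
    if bad:
        raise FormatError(f"unknown residue symbol(s) {sorted(bad)!r}")


def _profile(rows: list[str]) -> np.ndarray:
    """Column symbol-count matrix (L × |ALPHABET|) of aligned rows."""
    counts = np.zeros((len(rows[0]), len(ALPHABET)))
    for row in rows:
        for i, c in enumerate(row):
            counts[i, _INDEX[c]] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignParams
) -> tuple[list[str], list[str], float]:
    """Gotoh affine-gap global alignment of two profiles.

    The column-pair score is the mean residue-pair substitution score
    over all sequence pairs (gap symbols contributing 0).  Returns the
    two row sets with new gap columns inserted, plus the optimal score.
    Ties in the traceback are broken diagonal > up > left.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = pa.shape[0], pb.shape[0]
    na, nb = len(rows_a), len(rows_b)
    S = pa @ params.score_matrix @ pb.T / (na * nb)

    go, ge = params.gap_open, params.gap_extend
    neg = -np.inf
    # M: last column aligned; X: gap in B (consumes A, "up");
    # Y: gap in A (consumes B, "left").
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, m + 1):
            Xi[j] = max(Mi1[j] + go, Xi1[j] + ge, Yi1[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)
            Mi[j] = Si[j - 1] + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])

    # Traceback.  State preference on ties: M (diagonal) > X (up) > Y (left).
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax([finals[0], finals[1] - 1e-12, finals[2] - 2e-12]))
    # argmax with tiny penalties implements the strict preference order
    score = finals[state]
    ops: list[str] = []  # 'D' diagonal, 'U' up, 'L' left, reversed
    while i > 0 or j > 0:
        if state == 0:  # M
            ops.append("D")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
        elif state == 1:  # X
            ops.append("U")
            if i == 1 and j == 0:
                break
            prev = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            target = X[i, j]
            i -= 1
        else:  # Y
            ops.append("L")
            if j == 1 and i == 0:
                break
            prev = (M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
            target = Y[i, j]
            j -= 1
        if i == 0 and j == 0:
            break
        if state == 1:
            order = [(0, prev[0]), (1, prev[1]), (2, prev[2])]
        elif state == 2:
            # prev tuple above lists (M, Y, X) for state Y; map back
            order = [(0, prev[0]), (1, prev[2]), (2, prev[1])]
        else:
            order = [(0, prev[0]), (1, prev[1]), (2, prev[2])]
        for st, val in order:
            if np.isclose(val, target, rtol=0, atol=1e-9):
                state = st
                break
        else:  # pragma: no cover - numerical safety net
            raise RuntimeError("traceback failed to find predecessor state")

    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "U":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b, float(score)


def align_pair(
    seq1: str, seq2: str, params: AlignParams | None = None
) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two protein sequences.

    Returns ``(aligned1, aligned2, score)``.  Stripping gaps from the
    aligned strings recovers the inputs exactly.
    """
    if not seq1 or not seq2:
        raise ValueError("sequences must be non-empty")
    _validate_sequence(seq1)
    _validate_sequence(seq2)
    params = params or AlignParams()
    (a,), (b,), score = _align_profiles([seq1], [seq2], params)
    return a, b, score


def alignment_score(aligned1: str, aligned2: str, params: AlignParams | None = None) -> float:
    """Score an explicit pairwise alignment under the affine-gap model.

    Shared with the exhaustive-search tests so that the dynamic program
    and enumeration optimise the same objective.
    """
    params = params or AlignParams()
    m = params.score_matrix
    score = 0.0
    in_gap1 = in_gap2 = False
    for a, b in zip(aligned1, aligned2, strict=True):
        if a == GAP and b == GAP:
            raise ValueError("double-gap column in pairwise alignment")
        if a == GAP:
            score += params.gap_extend if in_gap1 else params.gap_open
            in_gap1, in_gap2 = True, False
        elif b == GAP:
            score += params.gap_extend if in_gap2 else params.gap_open
            in_gap2, in_gap1 = True, False
        else:
            score += m[_INDEX[a], _INDEX[b]]
            in_gap1 = in_gap2 = False
    return score


def _fraction_identity(aligned1: str, aligned2: str) -> float:
    ident = sum(
        1 for a, b in zip(aligned1, aligned2) if a == b and a != GAP
    )
    return ident / len(aligned1)


def align_group(
    group: OrthologueGroup, params: AlignParams | None = None
) -> MultipleAlignment:
    """Progressively align all isoforms of an orthologue group.

    Pairwise Needleman–Wunsch distances (1 − fraction identity) feed a
    UPGMA guide tree; profiles are merged leaf-to-root with
    profile–profile alignment.  All-gap columns are removed and row
    order follows the group's isoform order.
    """
    params = params or AlignParams()
    isoforms = group.isoforms
    if len(isoforms) == 1:
        return MultipleAlignment([(isoforms[0].isoform_id, isoforms[0].sequence)])

    n = len(isoforms)
    if n == 2:
        a, b, _ = align_pair(isoforms[0].sequence, isoforms[1].sequence, params)
        msa = MultipleAlignment(
            [(isoforms[0].isoform_id, a), (isoforms[1].isoform_id, b)]
        )
        return msa.drop_all_gap_columns()

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, _ = align_pair(isoforms[i].sequence, isoforms[j].sequence, params)
            dist[i, j] = dist[j, i] = 1.0 - _fraction_identity(a, b)
    tree = linkage(squareform(dist, checks=False), method="average")

    # node id -> (ordered member indices, aligned rows)
    nodes: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [isoforms[i].sequence]) for i in range(n)
    }
    for k, (left, right, _d, _cnt) in enumerate(tree):
        la, lr = nodes.pop(int(left))
        ra, rr = nodes.pop(int(right))
        new_l, new_r, _ = _align_profiles(lr, rr, params)
        nodes[n + k] = (la + ra, new_l + new_r)

    order, rows = nodes.popitem()[1]
    by_index = dict(zip(order, rows))
    msa = MultipleAlignment(
        [(isoforms[i].isoform_id, by_index[i]) for i in range(n)]
    )
    return msa.drop_all_gap_columns()


def ingest_alignment(path, group: OrthologueGroup) -> MultipleAlignment:
    """Load and validate a precomputed group alignment from aligned FASTA.

    Every group isoform must appear exactly once, rows must be equal
    length, and gap-stripping each row must reproduce the stored
    sequence.  All-gap columns are dropped (with a log note).
    """
    import logging

    records = read_fasta(path)
    ids = [rid for rid, _ in records]
    expected = set(group.isoform_ids)
    if set(ids) != expected or len(ids) != len(expected):
        raise FormatError(
            f"{path}: alignment ids {sorted(ids)} do not match group "
            f"isoforms {sorted(expected)}"
        )
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise FormatError(f"{path}: aligned rows have unequal lengths")
    by_id = dict(records)
    for iso in group.isoforms:
        stripped = by_id[iso.isoform_id].replace(GAP, "")
        if stripped != iso.sequence:
            raise FormatError(
                f"{path}: gap-stripped row for {iso.isoform_id!r} does not "
                "match its sequence"
            )
    msa = MultipleAlignment(
        [(iso.isoform_id, by_id[iso.isoform_id]) for iso in group.isoforms]
    )
    cleaned = msa.drop_all_gap_columns()
    if cleaned.length != msa.length:
        logging.getLogger(__name__).info(
            "%s: removed %d all-gap column(s)", path, msa.length - cleaned.length
        )
    return cleaned
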