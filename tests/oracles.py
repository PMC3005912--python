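"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately written from the rule statements alone,
with none of the package's data structures or shortcuts, so agreement
with the library is evidence the optimised paths are right.
"""

from itertools import combinations


def enumerate_alignments(s1: str, s2: str):
    """Yield every global alignment of s1 and s2 as (row1, row2) strings."""

    def rec(i, j):
        if i == len(s1) and j == len(s2):
            yield ("", "")
            return
        if i < len(s1) and j < len(s2):
            for a, b in rec(i + 1, j + 1):
                yield (s1[i] + a, s2[j] + b)
        if i < len(s1):
            for a, b in rec(i + 1, j):
                yield (s1[i] + a, "-" + b)
        if j < len(s2):
            for a, b in rec(i, j + 1):
                yield ("-" + a, s2[j] + b)

    return rec(0, 0)


def best_alignment_score(s1: str, s2: str, score_fn) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    return max(score_fn(a, b) for a, b in enumerate_alignments(s1, s2))


def brute_force_subcluster(ids_a, ids_b, sim, expand_on_tie=False):
    """Anchor-pair clustering executed literally from the rule statements.

    ids_a / ids_b are isoform ids per species; sim maps frozenset pairs
    to scores.  Returns a list of frozensets (the partition), anchored
    clusters first in creation order, then singletons.
    """
    remaining_a, remaining_b = set(ids_a), set(ids_b)
    clusters = []
    while remaining_a and remaining_b:
        candidates = [
            (sim[frozenset((a, b))], tuple(sorted((a, b))), a, b)
            for a in remaining_a
            for b in remaining_b
        ]
        best_score = max(c[0] for c in candidates)
        tied = sorted(c for c in candidates if c[0] == best_score)
        _, _, anchor_a, anchor_b = tied[0]
        members = {anchor_a, anchor_b}
        for m in remaining_a - {anchor_a}:
            s = sim[frozenset((m, anchor_a))]
            if s > best_score or (expand_on_tie and s == best_score):
                members.add(m)
        for m in remaining_b - {anchor_b}:
            s = sim[frozenset((m, anchor_b))]
            if s > best_score or (expand_on_tie and s == best_score):
                members.add(m)
        clusters.append(frozenset(members))
        remaining_a -= members
        remaining_b -= members
    for m in sorted(remaining_a | remaining_b):
        clusters.append(frozenset({m}))
    return clusters


def exact_ranksum_p_two_sided(x, y):
    """Two-sided permutation p-value of the Mann–Whitney U statistic,
    computed by full enumeration of label assignments with midranks."""

    def midranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    def u_of(xs, ys):
        pooled = list(xs) + list(ys)
        ranks = midranks(pooled)
        r1 = sum(ranks[: len(xs)])
        return r1 - len(xs) * (len(xs) + 1) / 2

    pooled = list(x) + list(y)
    n1 = len(x)
    mid = n1 * len(y) / 2
    u_obs = u_of(x, y)
    total = extreme = 0
    for chosen in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_of(xs, ys) - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return extreme / total
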