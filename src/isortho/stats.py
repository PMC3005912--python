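"""Wilcoxon rank-sum comparison of intra- vs inter-cluster differences.

Per-group average difference values (one intra and one inter value per
orthologue group) form two samples; the Mann–Whitney U / Wilcoxon
rank-sum test asks whether they come from the same distribution.  Small
samples (n1 + n2 <= 12) are tested against the exact permutation null
of the U statistic computed with midranks, which remains well defined
under ties; larger samples use the normal approximation with
tie-corrected variance and a continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .funcdiff import GroupDiffSummary

EXACT_LIMIT = 12


@dataclass
class RankSumResult:
    n1: int
    n2: int
    U: float
    z: float | None
    p_two_sided: float
    p_one_sided_greater: float
    method: str

    def as_dict(self) -> dict:
        return asdict(self)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann–Whitney U of sample x, midranks for ties."""
    n1 = len(x)
    ranks = rankdata(list(x) + list(y))
    r1 = float(np.sum(ranks[:n1]))
    return r1 - n1 * (n1 + 1) / 2.0


def rank_sum_test(x: Iterable[float], y: Iterable[float]) -> RankSumResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney U) test.

    Two-sided p by default; the one-sided p for "x tends larger than y"
    is also reported.
    """
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)

    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.asarray(x + y)
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        total = more_extreme = greater = 0
        idx = range(n1 + n2)
        for chosen in combinations(idx, n1):
            chosen_set = set(chosen)
            xs = pooled[list(chosen)]
            ys = pooled[[i for i in idx if i not in chosen_set]]
            u = _u_statistic(xs, ys)
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                more_extreme += 1
            if u >= u_obs - 1e-12:
                greater += 1
        return RankSumResult(
            n1=n1,
            n2=n2,
            U=u_obs,
            z=None,
            p_two_sided=more_extreme / total,
            p_one_sided_greater=greater / total,
            method="exact",
        )

    # Normal approximation, tie-corrected variance, continuity correction.
    n = n1 + n2
    _, counts = np.unique(np.asarray(x + y), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all observations identical
        return RankSumResult(
            n1=n1, n2=n2, U=u_obs, z=0.0, p_two_sided=1.0,
            p_one_sided_greater=1.0, method="normal_approx",
        )
    mean = n1 * n2 / 2.0
    dev = u_obs - mean
    z = (dev - math.copysign(0.5, dev)) / math.sqrt(var) if dev != 0 else 0.0
    p_two = min(1.0, 2.0 * norm.sf(abs(z)))
    z_greater = (u_obs - mean - 0.5) / math.sqrt(var)
    p_greater = float(norm.sf(z_greater))
    return RankSumResult(
        n1=n1,
        n2=n2,
        U=u_obs,
        z=float(z),
        p_two_sided=float(p_two),
        p_one_sided_greater=min(1.0, p_greater),
        method="normal_approx",
    )


def compare_measures(summaries: Iterable[GroupDiffSummary]) -> dict:
    """Per-measure intra/inter comparison across orthologue groups.

    For every measure present in the summaries, collects the defined
    intra and inter per-group means (dropping excluded groups and
    undefined sides), reports both distributions, their means, and the
    rank-sum test of inter vs intra.  JSON-serialisable.
    """
    by_measure: dict[str, list[GroupDiffSummary]] = {}
    for s in summaries:
        by_measure.setdefault(s.measure, []).append(s)

    report: dict[str, dict] = {}
    for measure, rows in sorted(by_measure.items()):
        active = [r for r in rows if not r.excluded]
        intra = [r.intra_mean for r in active if r.intra_mean is not None]
        inter = [r.inter_mean for r in active if r.inter_mean is not None]
        for side, values in (("intra", intra), ("inter", inter)):
            if not values:
                raise ValueError(
                    f"measure {measure!r}: no group has a defined {side} mean"
                )
        test = rank_sum_test(inter, intra)
        report[measure] = {
            "n_groups": len(rows),
            "n_excluded_all_equal": len(rows) - len(active),
            "n_intra_defined": len(intra),
            "n_inter_defined": len(inter),
            "intra_mean": float(np.mean(intra)),
            "inter_mean": float(np.mean(inter)),
            "intra_values": intra,
            "inter_values": inter,
            "rank_sum_inter_vs_intra": test.as_dict(),
        }
    return report
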