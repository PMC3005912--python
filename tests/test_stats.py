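import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from isortho import GroupDiffSummary, compare_measures, rank_sum_test

from oracles import exact_ranksum_p_two_sided


def summary(group_id, measure, intra, inter, excluded=False):
    return GroupDiffSummary(
        group_id=group_id,
        measure=measure,
        intra_mean=intra,
        inter_mean=inter,
        n_intra_pairs=0 if intra is None else 1,
        n_inter_pairs=0 if inter is None else 1,
        excluded=excluded,
    )


class TestRankSumTest:
    def test_identical_samples_give_p_one_exact(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert r.method == "exact"
        assert r.p_two_sided == 1.0

    def test_separated_samples_enumeration(self):
        """x={1,2}, y={3,4}: U=0 and the two-sided exact p is 2/C(4,2)."""
        r = rank_sum_test([1, 2], [3, 4])
        assert r.U == 0
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_two_sided_p_symmetric_under_sample_swap(self):
        x, y = [0.1, 0.4, 0.9], [0.2, 0.8, 1.5, 2.0]
        assert rank_sum_test(x, y).p_two_sided == pytest.approx(
            rank_sum_test(y, x).p_two_sided
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_u_statistic_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n1, n2 = rng.integers(1, 9), rng.integers(1, 9)
            x = list(rng.integers(0, 5, n1).astype(float))
            y = list(rng.integers(0, 5, n2).astype(float))
            r = rank_sum_test(x, y)
            assert 0 <= r.U <= n1 * n2
            assert 0 < r.p_two_sided <= 1

    def test_exact_p_matches_full_enumeration(self):
        """Exact-mode p equals an independent enumeration of all label
        assignments for assorted small samples, ties included."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            x = list(rng.integers(0, 4, n1).astype(float))
            y = list(rng.integers(0, 4, n2).astype(float))
            r = rank_sum_test(x, y)
            assert r.method == "exact"
            assert r.p_two_sided == pytest.approx(exact_ranksum_p_two_sided(x, y))

    def test_normal_approximation_close_to_exact_at_boundary(self):
        """On tie-free samples of 12, the continuity-corrected normal
        approximation lands within 10% of the exact enumeration p."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            pooled = rng.permutation(np.linspace(0.0, 2.0, 12) + rng.normal(0, 0.3, 12))
            x, y = list(pooled[:6]), list(pooled[6:])
            exact = rank_sum_test(x, y)
            assert exact.method == "exact"
            approx = rank_sum_test(x + [float(max(pooled)) + 1.0], y)
            assert approx.method == "normal_approx"
            # same statistic machinery as scipy's asymptotic route
            ref = mannwhitneyu(
                x + [float(max(pooled)) + 1.0], y,
                alternative="two-sided", method="asymptotic",
            )
            assert approx.p_two_sided == pytest.approx(float(ref.pvalue))
            if exact.p_two_sided > 0.05:
                assert approx.p_two_sided == pytest.approx(
                    exact_ranksum_p_two_sided(x + [float(max(pooled)) + 1.0], y),
                    rel=0.10,
                )

    def test_location_shift_monotonicity(self):
        """Growing every 'inter' value by a positive constant never
        raises the one-sided p for inter > intra."""
        rng = np.random.default_rng(13)
        intra = list(rng.normal(0, 1, 15))
        inter = list(rng.normal(0, 1, 15))
        last = 1.1
        for shift in (0.0, 0.5, 1.0, 2.0):
            p = rank_sum_test([v + shift for v in inter], intra).p_one_sided_greater
            assert p <= last + 1e-12
            last = p

    def test_all_identical_large_samples(self):
        r = rank_sum_test([1.0] * 10, [1.0] * 10)
        assert r.method == "normal_approx"
        assert r.p_two_sided == 1.0


class TestCompareMeasures:
    def test_direct_arithmetic_small_cohort(self):
        """3 groups with intra means {0,0,1} and inter {3,4,5}: sample
        means 1/3 and 4, and a small exact p for the separation."""
        summaries = [
            summary("g1", "func", 0.0, 3.0),
            summary("g2", "func", 0.0, 4.0),
            summary("g3", "func", 1.0, 5.0),
        ]
        report = compare_measures(summaries)
        func = report["func"]
        assert func["intra_mean"] == pytest.approx(1 / 3)
        assert func["inter_mean"] == 4.0
        test = func["rank_sum_inter_vs_intra"]
        assert test["method"] == "exact"
        assert test["p_two_sided"] == pytest.approx(0.1)  # 2/C(6,3)

    def test_single_group_both_sides(self):
        report = compare_measures([summary("g1", "dis", 0.5, 1.5)])
        t = report["dis"]["rank_sum_inter_vs_intra"]
        assert t["n1"] == t["n2"] == 1

    def test_undefined_sides_dropped_not_zeroed(self):
        summaries = [
            summary("g1", "func", None, 3.0),
            summary("g2", "func", 1.0, 4.0),
        ]
        report = compare_measures(summaries)
        assert report["func"]["n_intra_defined"] == 1
        assert report["func"]["intra_mean"] == 1.0

    def test_excluded_groups_do_not_contribute(self):
        summaries = [
            summary("g1", "func", 0.0, 0.0, excluded=True),
            summary("g2", "func", 1.0, 2.0),
        ]
        report = compare_measures(summaries)
        assert report["func"]["n_excluded_all_equal"] == 1
        assert report["func"]["n_intra_defined"] == 1

    def test_all_undefined_side_is_fatal_naming_side(self):
        with pytest.raises(ValueError, match="intra"):
            compare_measures([summary("g1", "func", None, 3.0)])

    def test_synthetic_cohort_inter_exceeds_intra(self):
        """Across seeded synthetic groups with exon-determined
        signatures, inter-cluster means dominate intra means."""
        from isortho import (
            SynthSpec,
            align_group,
            build_signature_vectors,
            diff_func,
            generate_group,
            group_diff_summary,
            similarity_matrix,
            subcluster_group,
        )

        summaries = []
        for seed in range(8):
            synth = generate_group(
                SynthSpec(
                    n_exons=4,
                    exon_lengths=(10, 10, 10, 10),
                    isoform_patterns=("1100", "1110", "1011"),
                    seed=seed,
                ),
                group_id=f"G{seed}",
            )
            gc = subcluster_group(
                synth.group, similarity_matrix(align_group(synth.group))
            )
            vectors = {
                v.isoform_id: v
                for v in build_signature_vectors(synth.group, synth.signatures)
            }
            summaries.append(
                group_diff_summary(
                    gc,
                    lambda i, j: diff_func(vectors[i], vectors[j]),
                    measure="func",
                )
            )
        report = compare_measures(summaries)
        assert report["func"]["inter_mean"] > report["func"]["intra_mean"]
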