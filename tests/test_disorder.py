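import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isortho import (
    DisorderAnnotation,
    FormatError,
    diff_dis,
    disorder_fraction,
    filter_regions,
    profile_from_annotation,
    scores_to_regions,
)

from conftest import DATA_DIR


def profile_with(n_regions, total_len, protein_len, iso="x"):
    """A DisorderProfile with a given region count and summed length,
    regions spaced 5 apart so the cleaning filters leave them alone."""
    regions, start = [], 1
    lengths = [10] * (n_regions - 1) + [total_len - 10 * (n_regions - 1)]
    for length in lengths:
        regions.append((start, start + length - 1))
        start += length + 5
    return filter_regions(regions, protein_len=protein_len, isoform_id=iso)


class TestScoresToRegions:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((0.9, 0.9, 0.1, 0.9), [(1, 2), (4, 4)]),
            ((0.1, 0.2, 0.3), []),
            ((0.8, 0.9, 0.7), [(1, 3)]),
            ((0.5,), [(1, 1)]),  # threshold is inclusive
        ],
    )
    def test_thresholded_runs(self, scores, expected):
        assert scores_to_regions(scores) == expected

    def test_custom_threshold(self):
        assert scores_to_regions((0.4, 0.4), threshold=0.3) == [(1, 2)]


class TestFilterRegions:
    def test_short_region_ignored(self):
        assert filter_regions([(1, 5)], protein_len=50).regions == []

    def test_nearby_regions_merged_then_kept(self):
        """Separation of 1 residue (< 3) merges two regions into one of
        length 25, which passes the 10-residue floor."""
        p = filter_regions([(1, 12), (14, 25)], protein_len=50)
        assert p.regions == [(1, 25)]
        assert p.n_regions == 1 and p.total_len == 25

    def test_separated_regions_kept_unchanged(self):
        p = filter_regions([(1, 12), (20, 35)], protein_len=50)
        assert p.regions == [(1, 12), (20, 35)]

    @pytest.mark.parametrize("sep,merged", [(0, True), (1, True), (2, True), (3, False)])
    def test_merge_boundary_is_strictly_below_three(self, sep, merged):
        first = (1, 12)
        second = (13 + sep, 24 + sep)
        p = filter_regions([first, second], protein_len=60)
        assert (p.n_regions == 1) == merged

    def test_merge_before_length_filter_rescues_fragments(self):
        """Two 6-residue fragments 1 apart merge into a 13-residue region
        under the default order but vanish if filtering comes first."""
        raw = [(1, 6), (8, 13)]
        default = filter_regions(raw, protein_len=30)
        assert default.regions == [(1, 13)]
        swapped = filter_regions(raw, protein_len=30, order="filter_then_merge")
        assert swapped.regions == []

    def test_overlapping_input_rejected(self):
        with pytest.raises(FormatError):
            filter_regions([(1, 12), (10, 25)], protein_len=50)

    def test_interval_outside_protein_rejected(self):
        with pytest.raises(FormatError):
            filter_regions([(1, 60)], protein_len=50)

    @given(
        raw=st.lists(
            st.tuples(st.integers(1, 80), st.integers(1, 20)), max_size=8
        ),
        min_len=st.integers(1, 15),
        merge_gap=st.integers(1, 6),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_idempotent_and_never_grows(self, raw, min_len, merge_gap):
        """Cleaning its own output changes nothing, and merging before
        filtering never increases the region count."""
        regions, last = [], 0
        for offset, length in raw:
            start = last + offset
            regions.append((start, start + length - 1))
            last = start + length - 1
        protein_len = (last or 1) + 5
        once = filter_regions(
            regions, protein_len=protein_len, min_len=min_len, merge_gap=merge_gap
        )
        again = filter_regions(
            once.regions, protein_len=protein_len, min_len=min_len, merge_gap=merge_gap
        )
        assert again.regions == once.regions
        assert once.n_regions <= len(regions)
        for (s1, e1), (s2, e2) in zip(once.regions, once.regions[1:]):
            assert s2 - e1 - 1 >= merge_gap
        assert all(e - s + 1 >= min_len for s, e in once.regions)


class TestDiffDis:
    def test_reference_region_counts(self):
        """9 vs 16 disordered regions differ by 7; equal counts by 0."""
        p9 = profile_with(9, 410, 950)
        p16 = profile_with(16, 616, 1432)
        assert diff_dis(p9, p16) == 7
        assert diff_dis(p9, profile_with(9, 403, 983)) == 0

    def test_empty_profile(self):
        p0 = filter_regions([], protein_len=100)
        p5 = profile_with(5, 60, 200)
        assert diff_dis(p0, p5) == 5

    def test_symmetry_and_triangle(self):
        a, b, c = (profile_with(n, n * 12, 500) for n in (3, 7, 11))
        assert diff_dis(a, b) == diff_dis(b, a)
        assert diff_dis(a, c) <= diff_dis(a, b) + diff_dis(b, c)


class TestDisorderFraction:
    def test_printed_reference_proportions(self):
        """Every reference-example row reproduces its printed disorder
        proportion at one-decimal precision, e.g. 67/150 -> 44.7%."""
        expected = {
            ("ENSP00000257247"): 44.7,
            ("ENSMUSP00000090632"): 64.9,
            ("ENSP00000367263"): 97.0,
            ("ENSMUSP00000090633"): 96.0,
            ("ENSMUSP00000051825"): 49.9,
            ("ENSMUSP00000093587"): 43.2,
            ("ENSP00000318783"): 41.0,
            ("ENSP00000356225"): 52.0,
            ("ENSMUSP00000039440"): 43.0,
            ("ENSP00000343925"): 45.8,
            ("ENSMUSP00000075932"): 53.6,
            ("ENSP00000351412"): 49.2,
            ("ENSMUSP00000098849"): 51.9,
        }
        with open(DATA_DIR / "reference_examples" / "disorder_counts.tsv") as fh:
            rows = {r["isoform_id"]: r for r in csv.DictReader(fh, delimiter="\t")}
        for iso, pct in expected.items():
            row = rows[iso]
            p = profile_with(
                int(row["n_regions"]), int(row["sum_len"]), int(row["protein_len"]), iso
            )
            assert p.n_regions == int(row["n_regions"])
            assert round(100 * disorder_fraction(p), 1) == pct

    def test_no_regions_gives_zero(self):
        assert disorder_fraction(filter_regions([], protein_len=80)) == 0.0

    def test_fully_disordered_gives_one(self):
        assert disorder_fraction(filter_regions([(1, 80)], protein_len=80)) == 1.0

    def test_zero_length_protein_rejected(self):
        with pytest.raises(ValueError):
            disorder_fraction(filter_regions([], protein_len=0))


class TestProfileFromAnnotation:
    def test_scores_dialect_thresholds_then_filters(self):
        scores = [0.9] * 12 + [0.1] * 5 + [0.9] * 4
        ann = DisorderAnnotation("p1", scores=scores)
        p = profile_from_annotation(ann)
        assert p.regions == [(1, 12)]  # trailing 4-mer too short
        assert p.protein_len == 21

    def test_intervals_dialect_defaults_protein_len(self):
        ann = DisorderAnnotation("p1", regions=[(1, 12)])
        p = profile_from_annotation(ann)
        assert p.protein_len == 12
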