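"""Profile grouping, replicate merging, nulls, strand flips, concordance
and heterozygosity."""

import numpy as np
import pytest

from minpanel.curation import (
    concordance_stats,
    find_systematic_nulls,
    group_identical_profiles,
    harmonize_strand,
    matrix_heterozygosity,
    merge_replicate_groups,
    sample_heterozygosity,
    summarize_by_ploidy,
)
from minpanel.errors import (
    AlignmentError,
    EmptyInputError,
    StrandAmbiguityError,
    UndefinedResultError,
)
from minpanel.simdata import SimConfig, simulate_collection
from minpanel.types import HET, HOM_X, HOM_Y, MISSING

from conftest import make_matrix


class TestGroupIdenticalProfiles:
    def test_clone_pair_plus_singleton(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2], [0, 1, 0]])
        groups = group_identical_profiles(m)
        sizes = sorted(g.size for g in groups)
        assert sizes == [1, 2]

    def test_missing_vs_called_strict_splits_compatible_merges(self):
        m = make_matrix([[0, 1], [0, -1]])
        strict = group_identical_profiles(m, "strict")
        assert len(strict) == 2
        with pytest.warns(UserWarning, match="over-merge|no-calls"):
            compat = group_identical_profiles(m, "compatible")
        assert len(compat) == 1

    def test_groups_partition_samples(self):
        cfg = SimConfig(n_founders=15, missing_rate=0.1, seed=3)
        obs, _ = simulate_collection(cfg)
        groups = group_identical_profiles(obs)
        members = [sid for g in groups for sid in g.member_sample_ids]
        assert sorted(members) == sorted(obs.sample_ids)

    def test_representatives_of_distinct_groups_differ(self):
        m = make_matrix([[0, 1], [0, 1], [2, 1], [0, -1]])
        groups = group_identical_profiles(m)
        reps = [tuple(g.representative_profile.tolist()) for g in groups]
        assert len(set(reps)) == len(reps)


class TestMergeReplicateGroups:
    def test_single_snp_difference_merges_labelled_replicates(self):
        # three same-label samples, one differing at one marker
        m = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0], [0, 1, 2, 2]])
        labels = {"S01": "BV", "S02": "BV", "S03": "BV"}
        groups = group_identical_profiles(m)
        assert len(groups) == 2
        merged, log = merge_replicate_groups(groups, labels, max_diff=1, matrix=m)
        assert len(merged) == 1
        assert merged[0].size == 3
        assert log[0].diff_count == 1

    def test_distant_same_label_profiles_not_merged(self):
        rows = [[0] * 21, [0] * 9 + [1] * 12]  # 12 differences
        m = make_matrix(rows)
        labels = {"S01": "K", "S02": "K"}
        groups = group_identical_profiles(m)
        merged, log = merge_replicate_groups(groups, labels, max_diff=2, matrix=m)
        assert len(merged) == 2
        assert log == []

    def test_unlabelled_groups_never_merge(self):
        m = make_matrix([[0, 1], [0, 2]])
        groups = group_identical_profiles(m)
        merged, _ = merge_replicate_groups(groups, {}, max_diff=5, matrix=m)
        assert len(merged) == 2

    def test_max_diff_zero_complete_profiles_matches_strict(self):
        m = make_matrix([[0, 1], [0, 1], [0, 2]])
        labels = {sid: "L" for sid in m.sample_ids}
        groups = group_identical_profiles(m)
        merged, _ = merge_replicate_groups(groups, labels, max_diff=0, matrix=m)
        assert len(merged) == len(groups)

    def test_unknown_sample_in_labels_warns(self):
        m = make_matrix([[0, 1], [0, 2]])
        groups = group_identical_profiles(m)
        with pytest.warns(UserWarning, match="unknown samples"):
            merge_replicate_groups(groups, {"ghost": "L"}, matrix=m)


class TestSystematicNulls:
    def test_shared_absence_flagged(self):
        m = make_matrix([[-1, 1, 0]] * 8)  # clonal group all missing marker 1
        groups = group_identical_profiles(m)
        assert groups[0].systematic_null_markers == ["M01"]
        assert find_systematic_nulls(groups[0], m) == ["M01"]

    def test_partial_absence_not_flagged(self):
        m = make_matrix([[-1, 1], [-1, 1], [-1, 1], [0, 1]])
        with pytest.warns(UserWarning):
            groups = group_identical_profiles(m, "compatible")
        nulls = find_systematic_nulls(groups[0], m)
        assert nulls == []

    def test_fully_called_group_has_no_nulls(self):
        m = make_matrix([[0, 1], [0, 1]])
        groups = group_identical_profiles(m)
        assert find_systematic_nulls(groups[0], m) == []

    def test_singleton_group_warns_and_returns_empty(self):
        m = make_matrix([[-1, 1]])
        groups = group_identical_profiles(m)
        with pytest.warns(UserWarning, match=">= 2"):
            assert find_systematic_nulls(groups[0], m) == []


class TestHarmonizeStrand:
    def test_opposite_strand_correspondence(self):
        # A/G scored on one strand reads C/T on the other:
        # A:A -> T:T, G:G -> C:C, A:G -> C:T (het stays het)
        calls = np.array([HOM_X, HOM_Y, HET, MISSING], dtype=np.int8)
        out = harmonize_strand(calls, ("A", "G"), ("C", "T"))
        # target pair is (C, T); complement of A is T = target allele_y
        assert out.tolist() == [HOM_Y, HOM_X, HET, MISSING]

    def test_missing_passes_through(self):
        out = harmonize_strand(np.array([MISSING]), ("A", "G"), ("C", "T"))
        assert out[0] == MISSING

    def test_palindromic_without_mapping_refused(self):
        for pair in (("A", "T"), ("C", "G")):
            with pytest.raises(StrandAmbiguityError):
                harmonize_strand(np.array([HOM_X]), pair, pair)

    def test_palindromic_with_explicit_mapping(self):
        out = harmonize_strand(
            np.array([HOM_X, HOM_Y]), ("A", "T"), ("A", "T"), mapping={"A": "T", "T": "A"}
        )
        assert out.tolist() == [HOM_Y, HOM_X]

    def test_involution(self):
        """Applying the inverse mapping restores the original calls."""
        rng = np.random.default_rng(1)
        calls = rng.integers(-1, 3, size=50).astype(np.int8)
        fwd = harmonize_strand(calls, ("A", "G"), ("C", "T"))
        back = harmonize_strand(fwd, ("C", "T"), ("A", "G"))
        assert np.array_equal(back, calls)

    def test_heterozygosity_invariant_under_harmonization(self):
        calls = np.array([HET, HET, HOM_X, HOM_Y, MISSING], dtype=np.int8)
        out = harmonize_strand(calls, ("A", "G"), ("C", "T"))
        assert sample_heterozygosity(out) == sample_heterozygosity(calls)


class TestConcordance:
    def test_self_comparison_is_hundred_percent(self):
        cfg = SimConfig(n_founders=10, missing_rate=0.1, seed=4)
        obs, _ = simulate_collection(cfg)
        rep = concordance_stats(obs, obs)
        assert rep.overall_percent == 100.0
        assert (rep.per_marker[["het_to_hom", "hom_to_het", "other_disagree"]] == 0).all().all()

    def test_het_called_hom_counted_per_marker(self):
        a = make_matrix([[1], [1], [1], [0]])
        b = make_matrix([[0], [2], [1], [0]])
        rep = concordance_stats(a, b)
        row = rep.per_marker.loc["M01"]
        assert row["het_to_hom"] == 2
        assert row["compared"] == 4
        assert row["agree"] == 2

    def test_one_disagreement_of_four(self):
        a = make_matrix([[0, 1], [2, 1]])
        b = make_matrix([[0, 1], [2, 0]])
        rep = concordance_stats(a, b)
        assert rep.overall_percent == 75.0

    def test_missing_excluded_from_denominator(self):
        a = make_matrix([[0, -1], [2, 1]])
        b = make_matrix([[0, 1], [-1, 1]])
        rep = concordance_stats(a, b)
        assert rep.compared == 2
        assert rep.overall_percent == 100.0

    def test_disagreement_symmetry(self):
        a = make_matrix([[1, 0], [2, 1], [1, 1]])
        b = make_matrix([[0, 0], [1, 1], [1, 2]])
        ab = concordance_stats(a, b)
        ba = concordance_stats(b, a)
        assert ab.per_marker["het_to_hom"].sum() == ba.per_marker["hom_to_het"].sum()
        assert ab.overall_percent == ba.overall_percent

    def test_shape_mismatch_raises_alignment_error(self):
        a = make_matrix([[0]], sample_ids=["S1"])
        b = make_matrix([[0]], sample_ids=["S2"])
        with pytest.raises(AlignmentError, match="S1|S2"):
            concordance_stats(a, b)

    def test_category_counts_sum_to_compared(self):
        rng = np.random.default_rng(8)
        a = make_matrix(rng.integers(-1, 3, size=(12, 5)).tolist())
        b = make_matrix(rng.integers(-1, 3, size=(12, 5)).tolist())
        rep = concordance_stats(a, b)
        total = (
            rep.per_marker["agree"]
            + rep.per_marker["het_to_hom"]
            + rep.per_marker["hom_to_het"]
            + rep.per_marker["other_disagree"]
        )
        assert (total == rep.per_marker["compared"]).all()


class TestHeterozygosity:
    def test_all_het_is_one(self):
        assert sample_heterozygosity(np.array([HET] * 5)) == 1.0

    def test_all_homozygous_is_zero(self):
        assert sample_heterozygosity(np.array([HOM_X, HOM_Y])) == 0.0

    def test_missing_excluded_from_denominator(self):
        p = np.array([HET] * 10 + [HOM_X] * 10 + [MISSING], dtype=np.int8)
        assert sample_heterozygosity(p) == 0.5

    def test_all_missing_undefined(self):
        with pytest.raises(UndefinedResultError):
            sample_heterozygosity(np.array([MISSING, MISSING]))

    def test_matrix_heterozygosity_matches_per_sample(self):
        m = make_matrix([[1, 1, 0], [0, 0, 2], [1, -1, 0]])
        series = matrix_heterozygosity(m)
        for sid in m.sample_ids:
            assert series[sid] == pytest.approx(sample_heterozygosity(m.profile(sid)))


class TestPloidySummary:
    def test_single_ploidy_mean_is_overall_mean(self):
        het = {"a": 0.2, "b": 0.4}
        summary = summarize_by_ploidy(het, {"a": 2, "b": 2}, tail_k=1)
        assert summary.groups.loc["2", "mean_heterozygosity"] == pytest.approx(0.3)
        assert summary.groups.loc["2", "n"] == 2

    def test_triploid_mean_exceeds_diploid_in_simulation(self):
        """Triploid-like heterozygosity inflation shows up in the summary."""
        cfg = SimConfig(
            n_founders=400, triploid_fraction=0.15, het_inflation=0.35, seed=77
        )
        obs, _ = simulate_collection(cfg)
        het = matrix_heterozygosity(obs)
        ploidy = {s.sample_id: s.reported_ploidy for s in obs.samples}
        summary = summarize_by_ploidy(het, ploidy, tail_k=100)
        assert (
            summary.groups.loc["3", "mean_heterozygosity"]
            > summary.groups.loc["2", "mean_heterozygosity"]
        )
        # the high-het tail is enriched for triploids relative to their share
        trip_share = summary.top_tail.get("3", 0) / summary.tail_k
        assert trip_share > 0.15

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_by_ploidy({}, {})
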