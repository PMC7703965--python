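"""Greedy panel selection, MAF, pair discrimination and the exhaustive oracle."""

import itertools

import numpy as np
import pytest

from minpanel.errors import ParameterError, UndefinedResultError, ValidationError
from minpanel.selection import (
    brute_force_minimum_panel,
    discriminated_pairs,
    greedy_select,
    minor_allele_frequency,
    rank_and_augment,
)
from minpanel.simdata import SimConfig, simulate_collection

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracle: rebuild the pairwise discrimination bookkeeping from
# scratch with plain sets, never touching the selection module's internals.
# ---------------------------------------------------------------------------


def oracle_pairs(column):
    """All-pairs scan: both called and different."""
    n = len(column)
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if column[i] >= 0 and column[j] >= 0 and column[i] != column[j]
    }


def oracle_greedy_replay(matrix, selected):
    """Recompute per-step gains for a given selection order."""
    unresolved = set(itertools.combinations(range(matrix.n_samples), 2))
    gains = []
    for mid in selected:
        col = matrix.marker_column(mid)
        newly = oracle_pairs(col) & unresolved
        gains.append(len(newly))
        unresolved -= newly
    return gains, unresolved


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 0, 0], 0.0),  # monomorphic
            ([0, 2], 0.5),  # balanced homozygotes
            ([0, 1, 1, -1], 2 / 6),  # hand count over non-missing calls
            ([1, 1], 0.5),  # all het
            ([2, 2, 1], 1 / 6),
        ],
    )
    def test_allele_counting(self, column, expected):
        assert minor_allele_frequency(np.array(column)) == pytest.approx(expected)

    def test_all_missing_undefined(self):
        with pytest.raises(UndefinedResultError):
            minor_allele_frequency(np.array([-1, -1]))

    def test_bounded_by_half(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            col = rng.integers(-1, 3, size=10)
            if (col >= 0).any():
                assert 0.0 <= minor_allele_frequency(col) <= 0.5


class TestDiscriminatedPairs:
    def test_monomorphic_splits_nothing(self):
        assert discriminated_pairs(np.array([0, 0, 0])) == set()

    def test_het_vs_hom_is_a_difference(self):
        assert discriminated_pairs(np.array([0, 1])) == {(0, 1)}

    def test_missing_never_discriminates(self):
        assert discriminated_pairs(np.array([0, -1, 2])) == {(0, 2)}

    def test_matches_oracle_on_random_columns(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            col = rng.integers(-1, 3, size=8)
            assert discriminated_pairs(col) == oracle_pairs(col)


class TestGreedySelect:
    def test_single_informative_marker(self):
        m = make_matrix([[0, 0], [0, 2]])  # only M02 splits the pair
        res = greedy_select(m)
        assert "M02" in res.selected
        assert res.residual_unresolved == []

    def test_clones_stay_unresolved(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        res = greedy_select(m)
        assert res.residual_unresolved == [("S01", "S02")]

    def test_first_marker_is_highest_maf(self):
        # M01 MAF 0.25, M02 MAF 0.5
        m = make_matrix([[0, 0], [0, 2], [0, 2], [1, 0]])
        res = greedy_select(m)
        assert res.selected[0] == "M02"

    def test_fewer_than_two_samples_rejected(self):
        m = make_matrix([[0, 1]])
        with pytest.raises(ParameterError):
            greedy_select(m)

    def test_max_panel_truncates(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.integers(0, 3, size=(10, 8)).tolist())
        res = greedy_select(m, max_panel=2)
        assert len(res.selected) <= 2

    def test_gains_match_oracle_on_simulated_instances(self):
        """Per-step gains equal a from-scratch pairwise recount, 25 seeds."""
        for seed in range(25):
            cfg = SimConfig(
                n_founders=6,
                n_markers=10,
                clone_group_sizes={1: 0.7, 2: 0.3},
                miscall_rate=0.0,
                missing_rate=0.05,
                sport_mutation_rate=0.0,
                seed=seed,
            )
            obs, _ = simulate_collection(cfg)
            res = greedy_select(obs)
            gains, unresolved = oracle_greedy_replay(obs, res.selected)
            assert res.gains == gains
            ids = obs.sample_ids
            assert set(res.residual_unresolved) == {
                (ids[i], ids[j]) for i, j in unresolved
            }

    def test_residual_pairs_truly_unsplittable(self):
        """Every leftover pair is split by NO marker in the matrix."""
        cfg = SimConfig(n_founders=8, n_markers=6, missing_rate=0.1, seed=42)
        obs, _ = simulate_collection(cfg)
        res = greedy_select(obs)
        ids = obs.sample_ids
        splittable = set()
        for j in range(obs.n_markers):
            splittable |= oracle_pairs(obs.calls[:, j])
        for a, b in res.residual_unresolved:
            assert (ids.index(a), ids.index(b)) not in splittable

    def test_cumulative_gains_strictly_positive_after_first(self):
        cfg = SimConfig(n_founders=10, n_markers=12, seed=5)
        obs, _ = simulate_collection(cfg)
        res = greedy_select(obs)
        assert all(g > 0 for g in res.gains[1:])

    def test_deterministic(self):
        cfg = SimConfig(n_founders=10, n_markers=12, seed=9)
        obs, _ = simulate_collection(cfg)
        r1, r2 = greedy_select(obs), greedy_select(obs)
        assert r1.selected == r2.selected
        assert r1.gains == r2.gains


class TestBruteForceMinimumPanel:
    def test_singleton_when_one_marker_suffices(self):
        m = make_matrix([[0, 0], [2, 0], [1, 0]])
        res = brute_force_minimum_panel(m, max_size=2)
        assert res.markers == ["M01"]

    def test_joint_two_marker_instance(self):
        # 5 samples: no single marker splits all pairs, M01+M02 jointly do
        m = make_matrix(
            [
                [0, 0, 0, 0],
                [2, 0, 0, 0],
                [0, 2, 0, 0],
                [2, 2, 0, 0],
                [1, 1, 0, 0],
            ]
        )
        res = brute_force_minimum_panel(m, max_size=3)
        assert res.markers == ["M01", "M02"]
        # exhaustive confirmation that no singleton works
        for j in range(4):
            assert len(oracle_pairs(m.calls[:, j])) < 10

    def test_identical_samples_reported_unresolvable(self):
        m = make_matrix([[0, 1], [0, 1]])
        res = brute_force_minimum_panel(m, max_size=2)
        assert res.markers is None
        assert "no marker" in res.reason

    def test_enumeration_guard(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.integers(0, 3, size=(4, 50)).tolist())
        with pytest.raises(ParameterError, match="greedy_select"):
            brute_force_minimum_panel(m, max_size=10, subset_guard=1000)

    def test_greedy_never_beats_optimum(self):
        """|greedy panel| >= |minimum panel| on feasible random instances."""
        for seed in range(15):
            cfg = SimConfig(
                n_founders=6, n_markers=7, missing_rate=0.05, seed=100 + seed
            )
            obs, _ = simulate_collection(cfg)
            greedy = greedy_select(obs)
            best = brute_force_minimum_panel(obs, max_size=obs.n_markers)
            if best.markers is not None:
                assert len(greedy.selected) >= len(best.markers)


class TestRankAndAugment:
    def _matrix(self):
        return make_matrix(
            [
                [0, 0, 0, 0],
                [2, 0, 2, 1],
                [1, 0, 2, 2],
                [0, 2, 1, 0],
            ],
            chromosomes=["chr1", "chr2", "chr2", "chr3"],
        )

    def test_all_chromosomes_covered_is_noop(self):
        m = make_matrix([[0, 0], [2, 2]], chromosomes=["chr1", "chr1"])
        sel = greedy_select(m)
        _, aug = rank_and_augment(m, sel)
        assert aug.selected == sel.selected

    def test_uncovered_chromosome_gets_best_scoring_candidate(self):
        m = self._matrix()
        sel = greedy_select(m, max_panel=1)
        ranking, aug = rank_and_augment(m, sel)
        added = [mid for mid in aug.selected if mid not in sel.selected]
        # recompute both candidates' scores by brute force per chromosome
        by_chrom = {}
        for r in ranking:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for chrom, cands in by_chrom.items():
            best = max(cands, key=lambda r: r.differentiation_score)
            appended = [mid for mid in added if mid in {c.marker_id for c in cands}]
            if appended:
                assert appended[0] == min(
                    (c for c in cands if c.differentiation_score == best.differentiation_score),
                    key=lambda r: r.marker_id,
                ).marker_id

    def test_missing_chromosome_labels_refused(self):
        m = make_matrix([[0, 0], [2, 2]])
        sel = greedy_select(m)
        with pytest.raises(ValidationError, match="chromosome"):
            rank_and_augment(m, sel)

    def test_one_marker_appended_per_uncovered_chromosome(self):
        m = self._matrix()
        sel = greedy_select(m, max_panel=1)
        covered = {"chr1", "chr2", "chr3"}
        _, aug = rank_and_augment(m, sel)
        chroms = {mk.chromosome for mk in m.markers if mk.marker_id in set(aug.selected)}
        assert chroms == covered
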