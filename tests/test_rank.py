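import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathrank import (
    GeneSet,
    PermutationScheme,
    RankProfile,
    RankTest,
    align_by_median,
    n_distinct_relabelings,
    permutation_pvalue,
    rank_statistic,
    rank_test_pathway,
    simulate_dataset,
    Scenario,
    within_subject_ranks,
)

from conftest import make_matrix
from oracles import (
    naive_align,
    naive_exhaustive_pvalue,
    naive_rank_matrix,
    naive_rank_statistic,
)


class TestAlignByMedian:
    def test_even_count_median(self):
        X = make_matrix([[1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0]])
        aligned = align_by_median(X)
        np.testing.assert_allclose(aligned.values[0], [-1.5, -0.5, 0.5, 1.5])

    def test_constant_row_maps_to_zero(self):
        X = make_matrix([[5.0, 5.0, 5.0, 5.0], [1, 2, 3, 4]])
        assert (align_by_median(X).values[0] == 0).all()

    def test_idempotent(self, random_matrix):
        once = align_by_median(random_matrix)
        twice = align_by_median(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert np.allclose(np.median(once.values, axis=1), 0.0)


class TestWithinSubjectRanks:
    def test_simple_ordering(self):
        X = make_matrix(np.array([[0.2], [-1.0], [0.5]]) @ np.ones((1, 4)))
        prof = within_subject_ranks(X)
        np.testing.assert_array_equal(prof.ranks[:, 0], [2, 1, 3])

    def test_midranks_for_ties(self):
        X = make_matrix(np.array([[1.0], [1.0], [0.0]]) @ np.ones((1, 4)))
        prof = within_subject_ranks(X)
        np.testing.assert_array_equal(prof.ranks[:, 0], [2.5, 2.5, 1])

    @given(
        arrays(
            np.float64,
            (7, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_rank_sum_identity(self, values):
        # midranks preserve the column sum M(M+1)/2 even under arbitrary ties
        prof = within_subject_ranks(make_matrix(values))
        np.testing.assert_allclose(prof.ranks.sum(axis=0), 7 * 8 / 2)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            within_subject_ranks(make_matrix(np.ones((1, 4))))


class TestRankStatistic:
    def test_hand_computed_distance(self):
        ranks = np.array([[1, 1, 3, 3], [2, 2, 2, 2], [3, 3, 1, 1]], dtype=float)
        prof = RankProfile(ranks=ranks, group_mask=[True, True, False, False])
        assert rank_statistic(prof) == pytest.approx(8.0)

    def test_zero_when_groups_identical(self):
        # same multiset of rank vectors split evenly across the groups
        ranks = np.array([[1, 2, 1, 2], [2, 1, 2, 1], [3, 3, 3, 3]], dtype=float)
        prof = RankProfile(ranks=ranks, group_mask=[True, True, False, False])
        assert rank_statistic(prof) == pytest.approx(0.0)

    def test_symmetric_in_group_labels(self, random_matrix):
        prof = within_subject_ranks(align_by_median(random_matrix))
        s1 = rank_statistic(prof, prof.group_mask)
        s2 = rank_statistic(prof, ~prof.group_mask)
        assert s1 == pytest.approx(s2)

    def test_invariant_under_common_gene_permutation(self, random_matrix):
        prof = within_subject_ranks(align_by_median(random_matrix))
        perm = np.random.default_rng(0).permutation(prof.m)
        shuffled = RankProfile(ranks=prof.ranks[perm, :], group_mask=prof.group_mask)
        assert rank_statistic(shuffled) == pytest.approx(rank_statistic(prof))

    def test_matches_naive_double_loop_on_46_gene_profile(self):
        rng = np.random.default_rng(7)
        X = make_matrix(rng.standard_normal((46, 10)), n1=5)
        aligned = align_by_median(X)
        prof = within_subject_ranks(aligned)
        naive = naive_rank_statistic(
            naive_rank_matrix(naive_align(X.values)), list(prof.group_mask)
        )
        assert rank_statistic(prof) == pytest.approx(naive)

    def test_empty_group_rejected(self):
        prof = RankProfile(ranks=np.ones((3, 4)), group_mask=[True] * 4)
        with pytest.raises(ValueError, match="both groups"):
            rank_statistic(prof)


class TestPermutationPvalue:
    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        X = make_matrix(rng.standard_normal((6, 6)), n1=3)
        prof = within_subject_ranks(align_by_median(X))
        res = permutation_pvalue(prof, PermutationScheme(n_perms=1000, seed=1))
        p_naive, total = naive_exhaustive_pvalue(prof.ranks, list(prof.group_mask))
        assert res.exhaustive
        assert res.n_perms_used == total == 20
        assert res.p_value == pytest.approx(p_naive)

    def test_strictly_largest_statistic_gives_one_over_total(self):
        # two clearly separated groups of 2: S_obs is the unique maximum
        ranks = np.array([[1, 1, 3, 3], [2, 2, 2, 2], [3, 3, 1, 1]], dtype=float)
        prof = RankProfile(ranks=ranks, group_mask=[True, True, False, False])
        res = permutation_pvalue(prof, PermutationScheme(n_perms=1000, seed=0))
        assert res.n_perms_used == n_distinct_relabelings(4, 2) == 6
        # the complementary labelling gives the same S, so 2 of 6 reach S_obs
        assert res.p_value == pytest.approx(2 / 6)

    def test_zero_statistic_gives_p_one(self):
        ranks = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 6))
        prof = RankProfile(ranks=ranks, group_mask=[True] * 3 + [False] * 3)
        res = permutation_pvalue(prof)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_random_regime_reproducible_and_bounded(self):
        rng = np.random.default_rng(5)
        X = make_matrix(rng.standard_normal((10, 16)), n1=8)
        prof = within_subject_ranks(align_by_median(X))
        scheme = PermutationScheme(n_perms=200, seed=11)
        r1 = permutation_pvalue(prof, scheme)
        r2 = permutation_pvalue(prof, scheme)
        assert not r1.exhaustive
        assert r1.n_perms_used == 200
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 200

    def test_null_pvalues_reject_at_nominal_rate(self):
        # both groups i.i.d.: rejection rate at alpha = 0.1 stays within
        # 3 binomial SEs of 0.1 over 500 replicates
        alpha, reps = 0.1, 500
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(reps):
            X = make_matrix(rng.standard_normal((15, 10)), n1=5)
            prof = within_subject_ranks(align_by_median(X))
            res = permutation_pvalue(prof, PermutationScheme(n_perms=1000, seed=1))
            rejections += res.p_value <= alpha
        rate = rejections / reps
        assert abs(rate - alpha) <= 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_midrank_stability_under_tiny_perturbation(self):
        # breaking a tie of size 2 by +/- eps moves each tied rank by 0.5
        values = np.array([[1.0, 0.0], [1.0, 0.5], [0.0, 1.0]])
        X = make_matrix(np.hstack([values, values]), n1=2)
        prof = within_subject_ranks(X)
        eps = 1e-9
        bumped = X.values.copy()
        bumped[0, 0] += eps
        prof_b = within_subject_ranks(make_matrix(bumped, n1=2))
        assert np.abs(prof.ranks - prof_b.ranks).max() <= 0.5 + 1e-12


class TestRankTestPathway:
    def test_identical_blocks_give_p_one(self):
        block = np.random.default_rng(0).standard_normal((8, 3))
        X = make_matrix(np.hstack([block, block]), n1=3)
        res = rank_test_pathway(X)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_to_which_group_is_first(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((12, 8))
        X1 = make_matrix(vals, n1=4, classes=("treated", "control"))
        X2 = make_matrix(vals, n1=4, classes=("control", "treated"))
        r1 = rank_test_pathway(X1, scheme=PermutationScheme(seed=4))
        r2 = rank_test_pathway(X2, scheme=PermutationScheme(seed=4))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_subset_then_test_matches_direct_call(self):
        X = simulate_dataset(Scenario(kind="mean_change", n_per_group=5), seed=1)
        g = GeneSet("half", frozenset(X.gene_ids[:20]))
        res = rank_test_pathway(X, g, PermutationScheme(seed=2))
        assert res.set_size == 20
        assert res.set_name == "half"

    def test_model_interface_matches_function(self, random_matrix):
        res_fn = rank_test_pathway(random_matrix, scheme=PermutationScheme(seed=3))
        res_m = RankTest(random_matrix).fit(n_perms=1000, seed=3)
        assert res_m.statistic == pytest.approx(res_fn.statistic)
        assert res_m.p_value == pytest.approx(res_fn.p_value)
        assert "Permutation p-value" in res_m.summary()
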