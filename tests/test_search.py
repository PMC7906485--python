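"""Subset enumeration, SCOMP intersection and the permutation search."""

import itertools
import math

import numpy as np
import pytest

from nbic import (
    Bicluster,
    LoadingMatrix,
    SearchConfig,
    compute_thresholds,
    enumerate_subsets,
    intersect_scomps,
    run_nbic,
    search_bic,
)
from nbic.search import sample_permutations
from nbic.simulate import SIM2_BLOCKS

BLOCK1_SUBJECTS = frozenset(SIM2_BLOCKS[0][0])


def brute_force_subsets(ids, K):
    """Oracle: power-set enumeration with the size gate."""
    out = set()
    for r in range(K, len(ids) + 1):
        out.update(frozenset(c) for c in itertools.combinations(ids, r))
    return out


class TestEnumerateSubsets:
    def test_dfs_order_on_three_ids(self):
        got = list(enumerate_subsets((1, 2, 3), 2))
        assert got == [(1, 2), (1, 2, 3), (1, 3), (2, 3)]

    def test_k_equal_to_length_yields_only_full_set(self):
        assert list(enumerate_subsets(tuple(range(6)), 6)) == [tuple(range(6))]

    def test_k_above_length_yields_nothing(self):
        assert list(enumerate_subsets((1, 2), 3)) == []

    def test_count_matches_binomial_sum(self):
        ids = tuple(range(10))
        got = list(enumerate_subsets(ids, 1))
        assert len(got) == 2**10 - 1
        for K in (2, 4, 7):
            expected = sum(math.comb(10, j) for j in range(K, 11))
            assert sum(1 for _ in enumerate_subsets(ids, K)) == expected

    @pytest.mark.parametrize("m,K", [(3, 2), (4, 2), (5, 3), (5, 1)])
    def test_matches_power_set_oracle_each_subset_once(self, m, K):
        ids = tuple(range(m))
        got = list(enumerate_subsets(ids, K))
        assert len(got) == len(set(map(frozenset, got)))  # exactly once
        assert set(map(frozenset, got)) == brute_force_subsets(ids, K)


class TestIntersectScomps:
    def test_identical_scomps_return_the_shared_set(self):
        scomps = {1: BLOCK1_SUBJECTS, 2: BLOCK1_SUBJECTS, 3: BLOCK1_SUBJECTS}
        assert intersect_scomps(scomps, {1, 2, 3}) == BLOCK1_SUBJECTS
        assert len(BLOCK1_SUBJECTS) == 13

    def test_disjoint_scomps_intersect_empty(self):
        scomps = {1: frozenset({1, 2}), 2: frozenset({3, 4})}
        assert intersect_scomps(scomps, {1, 2}) == frozenset()

    def test_single_feature_is_identity(self):
        scomps = {7: frozenset({5, 6})}
        assert intersect_scomps(scomps, {7}) == frozenset({5, 6})

    def test_unknown_feature_id_errors(self):
        with pytest.raises(KeyError):
            intersect_scomps({1: frozenset({1})}, {1, 99})


def _random_scomps(rng, m=5, n_subjects=12, density=0.5):
    return {
        fid + 1: frozenset(
            int(i) for i in np.flatnonzero(rng.random(n_subjects) < density)
        )
        for fid in range(m)
    }


class TestSearchBic:
    def test_three_disjoint_blocks_give_three_biclusters(self):
        # three features per block, all carrying that block's subject set;
        # cross-block intersections are empty, so only within-block triples
        # reach the N gate
        scomps = {}
        for b, (subjects, _) in enumerate(SIM2_BLOCKS):
            for k in range(3):
                scomps[3 * b + k + 1] = frozenset(subjects)
        config = SearchConfig(N=11, K=3, O=35)
        found = search_bic(tuple(range(1, 10)), scomps, config)
        assert len(found) == 3
        assert {b.subject_set for b in found} == {frozenset(s) for s, _ in SIM2_BLOCKS}

    def test_every_bicluster_meets_size_gates_and_exact_intersection(self, rng):
        scomps = _random_scomps(rng)
        config = SearchConfig(N=3, K=2, O=100)
        for b in search_bic((1, 2, 3, 4, 5), scomps, config):
            assert b.n_subjects >= 3 and b.n_features >= 2
            assert b.subject_set == intersect_scomps(scomps, b.feature_set)

    def test_candidate_set_is_permutation_invariant_before_validation(self, rng):
        # with the overlap gate disabled (O=100 blocks only exact duplicates,
        # impossible for distinct feature subsets), the accepted set equals
        # the brute-force power-set enumeration for every permutation
        scomps = _random_scomps(rng)
        config = SearchConfig(N=2, K=2, O=100)
        oracle = {
            (inter, fs)
            for fs in brute_force_subsets(tuple(scomps), 2)
            for inter in [intersect_scomps(scomps, fs)]
            if len(inter) >= 2
        }
        for perm in itertools.permutations(tuple(scomps)):
            got = {(b.subject_set, b.feature_set) for b in search_bic(perm, scomps, config)}
            assert got == oracle

    def test_monotonicity_larger_feature_set_never_larger_subject_set(self, rng):
        scomps = _random_scomps(rng, m=6)
        for fs in brute_force_subsets(tuple(scomps), 2):
            inter = intersect_scomps(scomps, fs)
            for wider in brute_force_subsets(tuple(scomps), 2):
                if fs < wider:
                    assert intersect_scomps(scomps, wider) <= inter

    def test_raising_n_or_k_never_increases_candidates(self, rng):
        scomps = _random_scomps(rng)
        perm = tuple(scomps)

        def count(N, K):
            return len(search_bic(perm, scomps, SearchConfig(N=N, K=K, O=100)))

        assert count(3, 2) >= count(4, 2) >= count(5, 2)
        assert count(3, 2) >= count(3, 3) >= count(3, 4)

    def test_non_bijective_permutation_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            search_bic((1, 1, 2), {1: frozenset({1}), 2: frozenset({2})}, SearchConfig())


class TestSamplePermutations:
    def test_small_m_enumerates_all_with_identity_first(self):
        perms = sample_permutations((1, 2, 3), budget=10, seed=0)
        assert len(perms) == 6
        assert perms[0] == (1, 2, 3)
        assert len(set(perms)) == 6

    def test_budget_caps_and_seeds_the_sample(self):
        ids = tuple(range(1, 9))
        a = sample_permutations(ids, budget=50, seed=7)
        b = sample_permutations(ids, budget=50, seed=7)
        c = sample_permutations(ids, budget=50, seed=8)
        assert a == b and a != c
        assert len(a) == 50 == len(set(a))
        assert a[0] == ids


class TestRunNbic:
    def test_fewer_features_than_k_errors(self, rng):
        matrix = LoadingMatrix(rng.uniform(-1, 1, (10, 2)), tuple(range(10)), ("a", "b"))
        with pytest.raises(ValueError, match="fewer features"):
            run_nbic(matrix, SearchConfig(K=3))

    def test_degenerate_identical_columns_collapse_to_small_family(self):
        values = np.tile(np.linspace(-1, 1, 8)[:, None], (1, 4))
        matrix = LoadingMatrix(values, tuple(range(8)), tuple("abcd"))
        config = SearchConfig(N=2, K=2, O=35, min_frequency=1, seed=0)
        bics = run_nbic(matrix, config)
        # every feature subset shares one subject set; feature-overlapping
        # candidates collapse into frequency-accumulated representatives,
        # leaving one entry per feature-disjoint pair ({a,b} and {c,d})
        assert len(bics) == 2
        assert len({b.subject_set for b in bics}) == 1
        # each permutation accepts exactly two feature-disjoint pairs
        assert sum(b.frequency for b in bics) == 2 * math.factorial(4)

    def test_same_seed_reproduces_identical_output(self, rng):
        values = rng.uniform(-1, 1, (25, 6))
        matrix = LoadingMatrix(values, tuple(range(25)), tuple("abcdef"))
        config = SearchConfig(N=4, K=2, O=35, min_frequency=1, seed=11, permutation_budget=100)
        assert run_nbic(matrix, config) == run_nbic(matrix, config)

    def test_output_uses_matrix_labels(self, rng):
        values = rng.uniform(-1, 1, (20, 4))
        matrix = LoadingMatrix(values, tuple(f"s{i}" for i in range(20)), tuple("wxyz"))
        bics = run_nbic(matrix, SearchConfig(N=2, K=2, O=35, min_frequency=1))
        assert bics
        for b in bics:
            assert b.feature_set <= set("wxyz")
            assert b.subject_set <= {f"s{i}" for i in range(20)}
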