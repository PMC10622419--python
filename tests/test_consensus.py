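"""Consensus clustering: elementary operations against brute-force oracles,
the CDF/delta-area arithmetic, and recovery/stability on planted cohorts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import brute_force_consensus, exhaustive_two_partition
from subtyper.consensus import (
    ConsensusClustering,
    assignment_summary,
    base_cluster,
    consensus_cdf,
    consensus_matrix,
    delta_areas,
    final_labels,
    pearson_distance,
    run_consensus,
    select_k,
    separation_score,
    subsample,
)
from subtyper.io import CohortMatrix
from subtyper.synthetic import SynthConfig, generate_profile_cohort
from conftest import two_group_cohort


class TestSubsample:
    def test_eighty_percent_of_ten(self):
        idx = subsample(10, 0.8, np.random.default_rng(0))
        assert len(idx) == 8 and len(set(idx)) == 8
        assert set(idx) <= set(range(10))

    def test_full_fraction_returns_all(self):
        np.testing.assert_array_equal(
            subsample(6, 1.0, np.random.default_rng(0)), np.arange(6))

    def test_reproducible_under_fixed_stream(self):
        a = subsample(50, 0.8, np.random.default_rng(42))
        b = subsample(50, 0.8, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_too_small_for_k(self):
        with pytest.raises(ValueError, match="cannot support K"):
            subsample(5, 0.5, np.random.default_rng(0), k=4)


class TestBaseCluster:
    def test_two_separated_groups_match_exhaustive_oracle(self):
        cohort = two_group_cohort(n_per_group=4, seed=3)
        X = cohort.data.to_numpy()
        labels = base_cluster(X, 2)
        oracle = exhaustive_two_partition(pearson_distance(X))
        assert adjusted_rand_score(labels, oracle) == 1.0

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        labels = base_cluster(X, 6)
        assert len(np.unique(labels)) == 6

    def test_duplicated_samples_co_assigned(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 5))
        X[3] = X[0]  # exact duplicate -> zero correlation distance
        labels = base_cluster(X, 3)
        assert labels[0] == labels[3]

    def test_constant_sample_gets_unit_distance(self):
        X = np.vstack([np.ones(5), np.random.default_rng(2).normal(size=(3, 5))])
        D = pearson_distance(X)
        np.testing.assert_allclose(D[0, 1:], 1.0)
        assert D[0, 0] == 0.0


class TestConsensusMatrix:
    def test_direct_count(self):
        # 2 samples co-sampled 4x, co-clustered 3x -> M = 0.75
        runs = [
            (np.array([0, 1]), np.array([0, 0])),
            (np.array([0, 1]), np.array([0, 0])),
            (np.array([0, 1]), np.array([0, 0])),
            (np.array([0, 1]), np.array([0, 1])),
        ]
        M = consensus_matrix(runs, 2)
        assert M[0, 1] == pytest.approx(0.75)
        assert M[0, 0] == M[1, 1] == 1.0

    def test_single_iteration_binary(self):
        runs = [(np.array([0, 1, 2]), np.array([0, 1, 0]))]
        M = consensus_matrix(runs, 3)
        assert set(np.unique(M[np.triu_indices(3, 1)])) <= {0.0, 1.0}

    def test_never_co_sampled_pair_zero(self):
        runs = [(np.array([0]), np.array([0])), (np.array([1]), np.array([0]))]
        M = consensus_matrix(runs, 2)
        assert M[0, 1] == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(9)
        runs = []
        for _ in range(15):
            subset = np.sort(rng.choice(8, size=6, replace=False))
            runs.append((subset, rng.integers(0, 3, size=6)))
        M = consensus_matrix(runs, 8)
        np.testing.assert_array_equal(M, brute_force_consensus(runs, 8))


class TestConsensusCdf:
    def test_all_zero_entries(self):
        _, _, area = consensus_cdf(np.eye(3))
        assert area == pytest.approx(1.0)

    def test_all_one_entries(self):
        _, _, area = consensus_cdf(np.ones((3, 3)))
        assert area == pytest.approx(0.0)

    def test_hand_riemann_sum(self):
        # entries {0, 0.5, 1} equally: CDF = (1/3, 2/3, 1);
        # left sum = 1/3*0.5 + 2/3*0.5 = 0.5
        M = np.array([
            [1.0, 0.0, 0.5, 1.0],
            [0.0, 1.0, 0.0, 0.5],
            [0.5, 0.0, 1.0, 1.0],
            [1.0, 0.5, 1.0, 1.0],
        ])
        # upper triangle: 0, 0.5, 1, 0, 0.5, 1 -> equal thirds
        _, _, area = consensus_cdf(M)
        assert area == pytest.approx(0.5)

    def test_cdf_monotone(self):
        rng = np.random.default_rng(4)
        M = rng.uniform(size=(10, 10))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        _, cdf, _ = consensus_cdf(M)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == pytest.approx(1.0)


class TestSelectK:
    def test_hand_arithmetic(self):
        areas = {2: 0.2, 3: 0.5, 4: 0.9, 5: 0.92, 6: 0.93}
        k, deltas = select_k(areas, tau=0.1)
        assert k == 4
        assert deltas[4] == pytest.approx((0.9 - 0.5) / 0.5)
        assert deltas[5] == pytest.approx((0.92 - 0.9) / 0.9)

    def test_flat_areas_fall_back_to_two(self):
        areas = {2: 0.5, 3: 0.5, 4: 0.5}
        k, _ = select_k(areas, tau=0.1)
        assert k == 2

    def test_delta_of_first_k_is_area(self):
        deltas = delta_areas({2: 0.3, 3: 0.6})
        assert deltas[2] == 0.3

    def test_needs_three_k_values(self):
        with pytest.raises(ValueError):
            select_k({2: 0.1, 3: 0.2})


class TestFinalLabels:
    def test_block_diagonal(self):
        M = np.zeros((6, 6))
        M[:3, :3] = 1.0
        M[3:, 3:] = 1.0
        labels = final_labels(M, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_renumbered_by_descending_size(self):
        M = np.zeros((5, 5))
        M[:2, :2] = 1.0   # small block
        M[2:, 2:] = 1.0   # large block
        labels = final_labels(M, 2)
        assert list(labels) == [1, 1, 0, 0, 0]  # label 0 = largest cluster


class TestRunConsensus:
    def test_seed_fixed_identical_result(self, small_cohort):
        cohort, _ = small_cohort
        r1 = run_consensus(cohort, k_range=range(2, 6), iters=30, seed=5)
        r2 = run_consensus(cohort, k_range=range(2, 6), iters=30, seed=5)
        assert r1.areas == r2.areas
        assert r1.assignment.labels.equals(r2.assignment.labels)
        for k in r1.k_range:
            np.testing.assert_array_equal(r1.consensus_matrices[k],
                                          r2.consensus_matrices[k])

    def test_single_iteration_entries_binary(self, small_cohort):
        cohort, _ = small_cohort
        res = run_consensus(cohort, k_range=range(2, 5), iters=1, seed=0)
        for k in res.k_range:
            M = res.consensus_matrices[k]
            vals = np.unique(M[np.triu_indices_from(M, 1)])
            assert set(np.round(vals, 12)) <= {0.0, 1.0}

    def test_matrix_invariants(self, small_cohort):
        cohort, _ = small_cohort
        res = run_consensus(cohort, k_range=range(2, 6), iters=25, seed=2)
        for k in res.k_range:
            M = res.consensus_matrices[k]
            np.testing.assert_array_equal(M, M.T)
            assert np.all((M >= 0) & (M <= 1))
            np.testing.assert_array_equal(np.diag(M), np.ones(len(M)))

    def test_oracle_equivalence_small(self):
        """n <= 8, iters <= 20: consensus matrices equal a brute-force
        recount of the logged iteration outputs, exactly."""
        cfg = SynthConfig(n_patients=8, n_metabolites=12, n_subtypes=2,
                          frac_informative=0.5, seed=13)
        cohort, _ = generate_profile_cohort(cfg, "tumor")
        res = run_consensus(cohort, k_range=range(2, 5), iters=20, seed=21,
                            keep_runs=True)
        for k in res.k_range:
            oracle = brute_force_consensus(res.runs[k], 8)
            np.testing.assert_array_equal(res.consensus_matrices[k], oracle)

    def test_recovery_at_effect_three(self):
        cfg = SynthConfig(n_patients=200, effect_size=3.0, seed=1)
        cohort, truth = generate_profile_cohort(cfg, "tumor")
        res = run_consensus(cohort, iters=100, seed=2)
        assert res.k_selected == 4
        ari = adjusted_rand_score(truth.tumor_subtype.to_numpy(),
                                  res.assignment.labels.to_numpy())
        assert ari >= 0.9

    def test_chance_level_at_zero_effect(self):
        cfg = SynthConfig(n_patients=200, effect_size=0.0, seed=1)
        cohort, truth = generate_profile_cohort(cfg, "tumor")
        res = run_consensus(cohort, k_range=range(2, 6), iters=60, seed=2)
        ari = adjusted_rand_score(truth.tumor_subtype.to_numpy(),
                                  res.labels_by_k[4])
        assert abs(ari) <= 0.1

    def test_reduced_iterations_select_same_k(self):
        """iters=100 agrees with iters=1000 on K* in >= 4/5 seeds."""
        cfg = SynthConfig(n_patients=80, seed=17)
        cohort, _ = generate_profile_cohort(cfg, "tumor")
        agree = 0
        for seed in range(5):
            k_small = run_consensus(cohort, iters=100, seed=seed).k_selected
            k_big = run_consensus(cohort, iters=1000, seed=1000 + seed).k_selected
            agree += k_small == k_big
        assert agree >= 4

    def test_sample_order_permutation_keeps_composition(self):
        cfg = SynthConfig(n_patients=60, seed=23)
        cohort, _ = generate_profile_cohort(cfg, "tumor")
        res1 = run_consensus(cohort, iters=60, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort.data))
        shuffled = CohortMatrix(data=cohort.data.iloc[perm],
                                compartment=cohort.compartment)
        res2 = run_consensus(shuffled, iters=60, seed=3)
        assert res1.k_selected == res2.k_selected
        c1 = res1.assignment.summary()["count"]
        c2 = res2.assignment.summary()["count"]
        assert sorted(c1.tolist()) == sorted(c2.tolist())


class TestAssignmentSummary:
    @pytest.mark.parametrize("counts, total, expected_pct", [
        ((91, 64, 81, 77), 313, (29, 20, 26, 25)),
        ((100, 71, 22, 75), 268, (37, 27, 8, 28)),
    ])
    def test_printed_cohort_percentages(self, counts, total, expected_pct):
        labels = []
        for i, c in enumerate(counts):
            labels += [f"T{i+1}"] * c
        summary = assignment_summary(pd.Series(labels))
        assert summary["count"].sum() == total
        assert tuple(summary["percent"]) == expected_pct

    def test_single_subtype_is_hundred_percent(self):
        summary = assignment_summary(pd.Series(["T1"] * 7))
        assert list(summary["percent"]) == [100]


class TestSeparationScore:
    def test_separated_groups_high_silhouette(self):
        cohort = two_group_cohort(n_per_group=6, seed=0)
        labels = np.array([0] * 6 + [1] * 6)
        assert separation_score(cohort, labels) >= 0.5

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(10, 1, size=(200, 20)),
                          index=[f"s{i}" for i in range(200)])
        cohort = CohortMatrix(data=df, compartment="tumor")
        labels = rng.integers(0, 4, size=200)
        assert abs(separation_score(cohort, labels)) <= 0.1

    def test_duplicated_points_perfect(self):
        df = pd.DataFrame(
            np.vstack([np.tile([1.0, 2.0, 4.0], (3, 1)),
                       np.tile([4.0, 2.0, 1.0], (3, 1))]),
            index=[f"s{i}" for i in range(6)])
        cohort = CohortMatrix(data=df, compartment="tumor")
        assert separation_score(cohort, np.array([0, 0, 0, 1, 1, 1])) == \
            pytest.approx(1.0)
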