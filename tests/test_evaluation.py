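"""Predictive power, permutation machinery, clustering and ARI."""

import numpy as np
import pytest
from scipy.special import comb

from scfc.core import FCMatrix, compute_fc, BoldTrace, connection_masks
from scfc.evaluation import (Partition, adjusted_rand, cluster_fc,
                             paired_permutation_test, permutation_test,
                             predictive_power, predictive_power_report)
from scfc.synthetic import SyntheticConfig, make_empirical_like_fc, make_sc


def _random_fc(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 4 * n))
    return compute_fc(BoldTrace(values=x, sampling_interval=2.0))


def ari_reference(labels_a, labels_b):
    """Independent contingency-table evaluation of the Hubert-Arabie ARI."""
    a_ids = np.unique(labels_a)
    b_ids = np.unique(labels_b)
    nij = np.array([[np.sum((labels_a == a) & (labels_b == b)) for b in b_ids]
                    for a in a_ids])
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    n = nij.sum()
    sum_ij = comb(nij, 2).sum()
    sum_a = comb(ai, 2).sum()
    sum_b = comb(bj, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestPredictivePower:
    def test_perfect_prediction_on_every_mask(self, small_sc):
        fc = _random_fc(20, 0)
        for mask in connection_masks(small_sc).values():
            assert predictive_power(fc, fc, mask) == pytest.approx(1.0)

    def test_sc_has_no_power_on_indirect_connections_by_definition(self, small_sc):
        fc = _random_fc(20, 1)
        mask = connection_masks(small_sc)["indirect"]
        assert predictive_power(small_sc, fc, mask) == 0.0

    def test_affine_invariance(self, small_sc):
        fc = _random_fc(20, 2)
        shifted = FCMatrix(values=np.clip(0.5 * fc.values + 0.2, -1, 1)
                           - np.diag(np.diag(0.5 * fc.values + 0.2)) + np.eye(20))
        mask = connection_masks(small_sc)["all"]
        assert predictive_power(shifted, fc, mask) == pytest.approx(1.0)

    def test_symmetric_in_arguments_and_reorder_invariant(self, small_sc, rng):
        a, b = _random_fc(20, 3), _random_fc(20, 4)
        mask = connection_masks(small_sc)["all"]
        assert predictive_power(a, b, mask) == pytest.approx(
            predictive_power(b, a, mask))
        perm = rng.permutation(20)
        a2 = FCMatrix(values=a.values[np.ix_(perm, perm)])
        b2 = FCMatrix(values=b.values[np.ix_(perm, perm)])
        assert predictive_power(a2, b2, mask) == pytest.approx(
            predictive_power(a, b, mask))

    def test_report_covers_all_classes(self, small_sc):
        emp, _ = make_empirical_like_fc(small_sc, 0.6, 240, seed=0)
        report = predictive_power_report(small_sc, emp, connection_masks(small_sc))
        assert set(report.r) == {"all", "direct", "indirect",
                                 "intrahemispheric", "interhemispheric"}
        assert report.r["indirect"] == 0.0
        assert report.variance_explained["all"] == report.r["all"] ** 2


class TestPermutationTest:
    def test_identical_matrices_reach_minimum_p(self, small_sc):
        fc = _random_fc(20, 5)
        mask = connection_masks(small_sc)["all"]
        p = permutation_test(fc, fc, mask, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_seed_determinism(self, small_sc):
        a, b = _random_fc(20, 6), _random_fc(20, 7)
        mask = connection_masks(small_sc)["all"]
        assert permutation_test(a, b, mask, 199, seed=3) == \
            permutation_test(a, b, mask, 199, seed=3)

    def test_type_one_error_is_calibrated(self):
        sc = make_sc(SyntheticConfig(n_regions=16, seed=0))
        mask = connection_masks(sc)["all"]
        hits = 0
        n_sims = 1000
        for i in range(n_sims):
            sim = _random_fc(16, 2 * i)
            emp = _random_fc(16, 2 * i + 1)
            if permutation_test(sim, emp, mask, n_perm=199, seed=i) <= 0.05:
                hits += 1
        assert 0.03 <= hits / n_sims <= 0.07


class TestPairedPermutationTest:
    def test_all_zero_differences_give_p_one(self):
        x = np.array([0.4, 0.5, 0.6, 0.7, 0.8])
        assert paired_permutation_test(x, x) == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_closed_form(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        b = a - 0.1  # all differences positive
        p = paired_permutation_test(a, b, alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_two_sided_p_is_symmetric_in_arguments(self, rng):
        a = rng.random(8)
        b = rng.random(8)
        assert paired_permutation_test(a, b) == pytest.approx(
            paired_permutation_test(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(5), np.ones(6))


class TestClusterFC:
    def test_recovers_perfect_block_structure(self):
        n, k = 24, 4
        labels_true = np.repeat(np.arange(1, k + 1), n // k)
        r = np.where(labels_true[:, None] == labels_true[None, :], 0.9, 0.0)
        np.fill_diagonal(r, 1.0)
        part = cluster_fc(FCMatrix(values=r), k)
        assert adjusted_rand(part, Partition(labels=labels_true)) == pytest.approx(1.0)

    def test_singleton_limit(self):
        fc = _random_fc(10, 8)
        part = cluster_fc(fc, 10)
        assert part.n_clusters == 10
        assert sorted(part.labels.tolist()) == list(range(1, 11))

    def test_requested_cluster_count_obtained(self):
        fc = _random_fc(40, 9)
        assert cluster_fc(fc, 10).n_clusters == 10

    def test_deterministic(self):
        fc = _random_fc(30, 10)
        assert np.array_equal(cluster_fc(fc, 5).labels, cluster_fc(fc, 5).labels)

    def test_out_of_range_k_rejected(self):
        fc = _random_fc(10, 11)
        with pytest.raises(ValueError):
            cluster_fc(fc, 1)
        with pytest.raises(ValueError):
            cluster_fc(fc, 11)


class TestAdjustedRand:
    def test_identical_partitions_and_relabelings_score_one(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        relabeled = np.array([3, 3, 1, 1, 2, 2])
        assert adjusted_rand(Partition(labels=labels),
                             Partition(labels=labels)) == pytest.approx(1.0)
        assert adjusted_rand(Partition(labels=labels),
                             Partition(labels=relabeled)) == pytest.approx(1.0)

    def test_worked_four_element_example(self):
        p1 = Partition(labels=np.array([1, 1, 2, 2]))  # {12|34}
        p2 = Partition(labels=np.array([1, 2, 1, 2]))  # {13|24}
        assert adjusted_rand(p1, p2) == pytest.approx(-0.5)

    def test_agrees_with_contingency_table_reference(self, rng):
        for _ in range(25):
            a = rng.integers(1, 5, size=30)
            b = rng.integers(1, 5, size=30)
            a = np.unique(a, return_inverse=True)[1] + 1
            b = np.unique(b, return_inverse=True)[1] + 1
            assert adjusted_rand(Partition(labels=a), Partition(labels=b)) == \
                pytest.approx(ari_reference(a, b))

    def test_chance_level_near_zero_for_random_partitions(self, rng):
        vals = []
        for _ in range(1000):
            a = np.unique(rng.integers(1, 11, size=160), return_inverse=True)[1] + 1
            b = np.unique(rng.integers(1, 11, size=160), return_inverse=True)[1] + 1
            vals.append(adjusted_rand(Partition(labels=a), Partition(labels=b)))
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand(Partition(labels=np.array([1, 2])),
                          Partition(labels=np.array([1, 2, 2])))
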