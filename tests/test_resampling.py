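"""Subsampling, connectivity/indicator matrices, and the consensus engine."""

import numpy as np
import pytest

from conclust import (
    AlgorithmSpec,
    ClusterAssignment,
    ExpressionMatrix,
    connectivity_matrix,
    consensus_cluster,
    indicator_matrix,
    subsample_rows,
)

SPEC = AlgorithmSpec("reference")


class TestSubsample:
    def test_proportion_08_draws_80_of_100(self):
        rng = np.random.default_rng(0)
        data = ExpressionMatrix(np.arange(200.0).reshape(100, 2),
                                [f"g{i}" for i in range(100)], ["a", "b"])
        subset, ids = subsample_rows(data, 0.8, rng)
        assert subset.n_features == 80
        assert len(set(ids)) == 80

    def test_full_proportion_is_identity(self, tiny_matrix):
        rng = np.random.default_rng(0)
        subset, ids = subsample_rows(tiny_matrix, 1.0, rng)
        assert ids == tiny_matrix.feature_ids
        assert np.array_equal(subset.values, tiny_matrix.values)

    def test_seeded_draws_are_reproducible(self):
        data = ExpressionMatrix(np.arange(20.0).reshape(10, 2),
                                [f"g{i}" for i in range(10)], ["a", "b"])
        ids1 = subsample_rows(data, 0.5, np.random.default_rng(3))[1]
        ids2 = subsample_rows(data, 0.5, np.random.default_rng(3))[1]
        assert ids1 == ids2

    @pytest.mark.parametrize("proportion", [0.0, -0.2, 1.5])
    def test_invalid_proportion_rejected(self, tiny_matrix, proportion):
        with pytest.raises(ValueError):
            subsample_rows(tiny_matrix, proportion, np.random.default_rng(0))


class TestConnectivityIndicator:
    def test_connectivity_direct_definition(self):
        a = ClusterAssignment({"a": 1, "b": 1, "c": 2}, 2, SPEC)
        conn = connectivity_matrix(a, ["a", "b", "c"])
        assert conn[0, 1] == 1 and conn[0, 2] == 0 and conn[1, 2] == 0
        assert np.array_equal(conn, conn.T)
        assert conn[0, 0] == conn[1, 1] == conn[2, 2] == 1

    def test_single_cluster_gives_all_ones(self):
        a = ClusterAssignment({"a": 1, "b": 1, "c": 1}, 1, SPEC)
        conn = connectivity_matrix(a, ["a", "b", "c"])
        assert np.array_equal(conn, np.ones((3, 3), dtype=int))

    def test_unsampled_features_are_zero_rows(self):
        a = ClusterAssignment({"a": 1, "b": 2, "c": 2}, 2, SPEC)
        conn = connectivity_matrix(a, ["a", "b", "c", "d"])
        assert conn[3].sum() == 0 and conn[:, 3].sum() == 0
        assert conn[1, 2] == 1

    def test_unknown_id_rejected(self):
        a = ClusterAssignment({"z": 1}, 1, SPEC)
        with pytest.raises(ValueError, match="universe"):
            connectivity_matrix(a, ["a", "b"])

    def test_indicator_direct_definition(self):
        ind = indicator_matrix(["a", "b"], ["a", "b", "c"])
        assert ind[0, 1] == 1 and ind[0, 2] == 0 and ind[1, 2] == 0
        assert np.array_equal(ind, ind.T)

    def test_indicator_full_and_empty_sample(self):
        assert np.array_equal(indicator_matrix(["a", "b"], ["a", "b"]),
                              np.ones((2, 2), dtype=int))
        assert indicator_matrix([], ["a", "b"]).sum() == 0


class TestConsensusEngine:
    def test_no_sampling_variation_gives_binary_matrix(self, two_clouds):
        result = consensus_cluster(two_clouds, AlgorithmSpec("kmedoids"), 2,
                                   iterations=5, proportion=1.0, seed=0)
        off = result.matrix[~np.eye(20, dtype=bool)]
        assert set(np.unique(off)) <= {0.0, 1.0}

    def test_quotient_by_definition(self):
        # consensus entry must equal co-cluster count / co-sample count
        rng = np.random.default_rng(5)
        data = ExpressionMatrix(rng.normal(size=(12, 3)),
                                [f"g{i}" for i in range(12)], ["a", "b", "c"])
        result = consensus_cluster(data, AlgorithmSpec("hierarchical"), 3,
                                   iterations=20, proportion=0.6, seed=1)
        with np.errstate(invalid="ignore"):
            expected = result.connectivity_sum / result.indicator_sum
        mask = result.indicator_sum > 0
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(result.matrix[mask & off], expected[mask & off])

    def test_matches_bruteforce_pair_counting_oracle(self):
        # the engine's consensus matrix must equal a naive double-loop
        # recount over the logged per-iteration assignments
        rng = np.random.default_rng(7)
        data = ExpressionMatrix(rng.normal(size=(12, 4)),
                                [f"g{i}" for i in range(12)],
                                ["c1", "c2", "c3", "c4"])
        result = consensus_cluster(data, AlgorithmSpec("kmedoids"), 3,
                                   iterations=50, proportion=0.75, seed=11,
                                   keep_assignments=True)
        ids = result.feature_ids
        n = len(ids)
        conn = np.zeros((n, n))
        ind = np.zeros((n, n))
        for sampled, assignment in result.assignments:
            in_sample = set(sampled)
            for i in range(n):
                for j in range(n):
                    if ids[i] in in_sample and ids[j] in in_sample:
                        ind[i, j] += 1
                        if assignment.labels[ids[i]] == assignment.labels[ids[j]]:
                            conn[i, j] += 1
        expected = np.divide(conn, ind, out=np.zeros((n, n)), where=ind > 0)
        np.fill_diagonal(expected, 1.0)
        assert np.array_equal(result.connectivity_sum, conn.astype(int))
        assert np.array_equal(result.indicator_sum, ind.astype(int))
        assert np.array_equal(result.matrix, expected)

    def test_conservation_invariant(self, two_clouds):
        result = consensus_cluster(two_clouds, AlgorithmSpec("hierarchical"), 2,
                                   iterations=30, proportion=0.7, seed=3)
        assert np.all(result.connectivity_sum <= result.indicator_sum)
        assert np.all(result.indicator_sum <= result.iterations)
        off = ~np.eye(20, dtype=bool)
        assert result.matrix[off].min() >= 0 and result.matrix[off].max() <= 1
        assert np.allclose(np.diag(result.matrix), 1.0)
        assert np.allclose(result.matrix, result.matrix.T)

    def test_reference_uses_full_data_same_conditions(self, two_clouds):
        spec = AlgorithmSpec("kmedoids")
        result = consensus_cluster(two_clouds, spec, 2, iterations=5,
                                   proportion=0.8, seed=9)
        assert set(result.reference.labels) == set(two_clouds.feature_ids)
        assert result.reference.k == 2
        assert result.reference.algorithm == spec

    def test_order_independent_seeding(self, two_clouds):
        a = consensus_cluster(two_clouds, AlgorithmSpec("hierarchical"), 2,
                              iterations=10, proportion=0.8, seed=21)
        b = consensus_cluster(two_clouds, AlgorithmSpec("hierarchical"), 2,
                              iterations=10, proportion=0.8, seed=21)
        assert np.array_equal(a.matrix, b.matrix)

    def test_subsample_below_k_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="fewer than k"):
            consensus_cluster(tiny_matrix, AlgorithmSpec("kmedoids"), 2,
                              iterations=2, proportion=0.34, seed=0)
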