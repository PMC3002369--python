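"""Cluster and membership robustness against brute-force oracles."""

import numpy as np
import pytest

from conclust import (
    AlgorithmSpec,
    ClusterAssignment,
    cluster_robustness,
    membership_robustness,
    robustness_report,
)
from conftest import random_assignment, random_consensus_matrix

SPEC = AlgorithmSpec("reference")


def wrap(matrix, ids):
    class _M:
        pass

    m = _M()
    m.matrix = matrix
    m.feature_ids = list(ids)
    return m


def brute_cluster_robustness(m, ids, reference):
    """Nested-loop mean of within-cluster upper-triangle entries."""
    pos = {f: i for i, f in enumerate(ids)}
    out = {}
    for c, members in reference.cluster_index_sets.items():
        p = sorted(pos[f] for f in members)
        total, count = 0.0, 0
        for a in range(len(p)):
            for b in range(a + 1, len(p)):
                total += m[p[a], p[b]]
                count += 1
        out[c] = total / count if count else 1.0
    return out


def brute_membership_robustness(m, ids, reference):
    pos = {f: i for i, f in enumerate(ids)}
    out = {}
    for c, members in reference.cluster_index_sets.items():
        for f in members:
            total = sum(m[pos[f], pos[g]] for g in members if g != f)
            out[(c, f)] = total / (len(members) - 1) if len(members) > 1 else 1.0
    return out


class TestDirectArithmetic:
    """Worked three-member cluster: M(a,b)=1, M(a,c)=0.5, M(b,c)=0.5."""

    @pytest.fixture
    def three_member(self):
        m = np.array([[1.0, 1.0, 0.5],
                      [1.0, 1.0, 0.5],
                      [0.5, 0.5, 1.0]])
        ref = ClusterAssignment({"a": 1, "b": 1, "c": 1}, 1, SPEC)
        return wrap(m, ["a", "b", "c"]), ref

    def test_cluster_robustness_value(self, three_member):
        matrix, ref = three_member
        assert cluster_robustness(matrix, ref)[1] == pytest.approx(2 / 3)

    def test_membership_robustness_values(self, three_member):
        matrix, ref = three_member
        mr = membership_robustness(matrix, ref)
        assert mr[(1, "a")] == pytest.approx(0.75)
        assert mr[(1, "b")] == pytest.approx(0.75)
        assert mr[(1, "c")] == pytest.approx(0.5)

    def test_cluster_is_mean_of_members(self, three_member):
        matrix, ref = three_member
        mr = membership_robustness(matrix, ref)
        assert np.mean(list(mr.values())) == pytest.approx(
            cluster_robustness(matrix, ref)[1], abs=1e-12
        )

    def test_perfect_consensus_gives_one(self):
        matrix = wrap(np.ones((4, 4)), list("abcd"))
        ref = ClusterAssignment({f: 1 for f in "abcd"}, 1, SPEC)
        assert cluster_robustness(matrix, ref)[1] == 1.0


class TestOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(8)]
        m = random_consensus_matrix(8, rng)
        ref = random_assignment(ids, 2, rng)
        matrix = wrap(m, ids)
        cr = cluster_robustness(matrix, ref)
        mr = membership_robustness(matrix, ref)
        assert cr == pytest.approx(brute_cluster_robustness(m, ids, ref),
                                   abs=1e-12)
        assert mr == pytest.approx(brute_membership_robustness(m, ids, ref),
                                   abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_mean_equivalence_invariant(self, seed):
        # m(k) equals the mean of its members' m_i(k) on every
        # non-singleton cluster — exact algebra, checked to 1e-12
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 12))
        k = int(rng.integers(2, n // 2 + 1))
        ids = [f"g{i}" for i in range(n)]
        matrix = wrap(random_consensus_matrix(n, rng), ids)
        ref = random_assignment(ids, k, rng)
        cr = cluster_robustness(matrix, ref)
        mr = membership_robustness(matrix, ref)
        for c, members in ref.cluster_index_sets.items():
            if len(members) < 2:
                continue
            member_mean = np.mean([mr[(c, f)] for f in members])
            assert abs(cr[c] - member_mean) < 1e-12

    def test_monotonicity_in_within_cluster_entry(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(6)]
        m = random_consensus_matrix(6, rng)
        ref = ClusterAssignment(dict(zip(ids, [1, 1, 1, 2, 2, 2])), 2, SPEC)
        base_cr = cluster_robustness(wrap(m, ids), ref)[1]
        base_mr = membership_robustness(wrap(m, ids), ref)[(1, "g0")]
        bumped = m.copy()
        bumped[0, 1] = bumped[1, 0] = min(1.0, m[0, 1] + 0.2)
        assert cluster_robustness(wrap(bumped, ids), ref)[1] >= base_cr
        assert membership_robustness(wrap(bumped, ids), ref)[(1, "g0")] >= base_mr


class TestReportAndConventions:
    def test_singleton_convention_and_flag(self):
        m = np.array([[1.0, 0.3, 0.3],
                      [0.3, 1.0, 0.9],
                      [0.3, 0.9, 1.0]])
        ref = ClusterAssignment({"a": 1, "b": 2, "c": 2}, 2, SPEC)
        report = robustness_report(wrap(m, ["a", "b", "c"]), ref)
        assert report.cluster_robustness[1] == 1.0
        assert report.membership_robustness[(1, "a")] == 1.0
        assert report.singleton_flags == {1}

    def test_same_reference_castable_onto_different_matrices(self):
        # the casting contract: one structure scored against two matrices
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(6)]
        ref = random_assignment(ids, 2, rng)
        m1 = random_consensus_matrix(6, rng)
        m2 = random_consensus_matrix(6, rng)
        r1 = robustness_report(wrap(m1, ids), ref, source="consensus")
        r2 = robustness_report(wrap(m2, ids), ref, source="merge")
        assert r1.reference is ref and r2.reference is ref
        assert set(r1.membership_robustness) == set(r2.membership_robustness)

    def test_tidy_frame_columns(self):
        ref = ClusterAssignment({"a": 1, "b": 1}, 1, SPEC)
        report = robustness_report(wrap(np.ones((2, 2)), ["a", "b"]), ref)
        frame = report.to_frame()
        assert list(frame.columns) == [
            "cluster", "feature_id", "membership_robustness",
            "cluster_robustness", "singleton_flag", "source",
        ]

    def test_mismatched_ids_rejected(self):
        ref = ClusterAssignment({"x": 1, "y": 1}, 1, SPEC)
        with pytest.raises(ValueError, match="feature ids"):
            cluster_robustness(wrap(np.ones((2, 2)), ["a", "b"]), ref)

    def test_values_bounded(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(10)]
        report = robustness_report(
            wrap(random_consensus_matrix(10, rng), ids),
            random_assignment(ids, 3, rng),
        )
        values = list(report.cluster_robustness.values()) + list(
            report.membership_robustness.values()
        )
        assert all(0.0 <= v <= 1.0 for v in values)
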