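"""Cluster and membership robustness from a consensus-type matrix.

Both statistics score a *reference* partition against a consensus (or merged)
matrix ℳ.  For cluster k with member index set I_k of size N_k:

    cluster robustness      m(k)   = Σ_{i<j ∈ I_k} ℳ(i,j) / (N_k (N_k − 1) / 2)
    membership robustness   m_i(k) = Σ_{j ∈ I_k, j≠i} ℳ(i,j) / (N_k − 1)

i.e. the mean within-cluster consensus over unordered member pairs, and the
mean consensus between one member and the rest of its cluster.  The diagonal
is excluded throughout.  m(k) is exactly the mean of its members' m_i(k) —
a useful algebraic cross-check.

The reference structure is supplied explicitly (it is NOT re-derived by
clustering the consensus matrix), so the same partition can be scored against
a single-algorithm consensus and against a merge, making the two directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .algorithms import ClusterAssignment

__all__ = [
    "RobustnessReport",
    "cluster_robustness",
    "membership_robustness",
    "robustness_report",
]

#: value assigned to singleton clusters, whose pair sums are empty; a
#: singleton is vacuously self-consistent, and the flag in the report keeps
#: the convention visible.
SINGLETON_VALUE = 1.0


def _coerce_matrix(matrix, reference: ClusterAssignment) -> tuple[np.ndarray, list[str]]:
    feature_ids = getattr(matrix, "feature_ids", None)
    m = np.asarray(getattr(matrix, "matrix", matrix), dtype=float)
    if feature_ids is None:
        feature_ids = sorted(reference.labels)
        if m.shape[0] != len(feature_ids):
            raise ValueError("bare matrix size does not match the reference; "
                             "pass a consensus/merge result carrying feature_ids")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("consensus matrix must be symmetric")
    if m.min() < -1e-12 or m.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    if set(feature_ids) != set(reference.labels):
        raise ValueError("matrix feature ids do not match the reference clustering")
    return m, list(feature_ids)


def cluster_robustness(matrix, reference: ClusterAssignment) -> dict[int, float]:
    """Mean within-cluster consensus m(k) for every cluster of the reference."""
    m, ids = _coerce_matrix(matrix, reference)
    pos = {f: i for i, f in enumerate(ids)}
    out: dict[int, float] = {}
    for c, members in sorted(reference.cluster_index_sets.items()):
        p = np.array(sorted(pos[f] for f in members))
        nk = len(p)
        if nk == 1:
            out[c] = SINGLETON_VALUE
            continue
        sub = m[np.ix_(p, p)]
        upper = sub[np.triu_indices(nk, k=1)]
        out[c] = float(upper.sum() / (nk * (nk - 1) / 2))
    return out


def membership_robustness(matrix, reference: ClusterAssignment
                          ) -> dict[tuple[int, str], float]:
    """Per-member mean consensus m_i(k), keyed by (cluster, feature id)."""
    m, ids = _coerce_matrix(matrix, reference)
    pos = {f: i for i, f in enumerate(ids)}
    out: dict[tuple[int, str], float] = {}
    for c, members in sorted(reference.cluster_index_sets.items()):
        ordered = sorted(members, key=lambda f: pos[f])
        p = np.array([pos[f] for f in ordered])
        nk = len(p)
        if nk == 1:
            out[(c, ordered[0])] = SINGLETON_VALUE
            continue
        sub = m[np.ix_(p, p)]
        row_sums = sub.sum(axis=1) - np.diag(sub)
        for f, s in zip(ordered, row_sums):
            out[(c, f)] = float(s / (nk - 1))
    return out


@dataclass
class RobustnessReport:
    """Tidy bundle of m(k) and m_i(k) for one (matrix, reference) pairing."""

    cluster_robustness: dict[int, float]
    membership_robustness: dict[tuple[int, str], float]
    reference: ClusterAssignment
    source: str
    singleton_flags: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c,
                "feature_id": f,
                "membership_robustness": v,
                "cluster_robustness": self.cluster_robustness[c],
                "singleton_flag": c in self.singleton_flags,
                "source": self.source,
            }
            for (c, f), v in sorted(self.membership_robustness.items())
        ]
        return pd.DataFrame(rows)


def robustness_report(matrix, reference: ClusterAssignment,
                      source: str = "consensus") -> RobustnessReport:
    """Compute both robustness statistics and flag singleton clusters."""
    cr = cluster_robustness(matrix, reference)
    mr = membership_robustness(matrix, reference)
    singletons = {c for c, n in reference.cluster_sizes.items() if n == 1}
    return RobustnessReport(cr, mr, reference, source, singletons)
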