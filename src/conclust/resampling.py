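"""Consensus clustering by row resampling.

The engine repeatedly draws a subsample of rows (without replacement),
clusters the subsample, and accumulates two N×N tallies: the *connectivity*
sum counts iterations in which a pair of features landed in the same cluster,
and the *indicator* sum counts iterations in which the pair was drawn
together at all.  Their elementwise quotient is the consensus matrix ℳ —
the empirical frequency with which two features co-cluster given the
opportunity.  A reference clustering of the full data under identical
conditions is carried along so robustness can later be scored against a
concrete partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .algorithms import AlgorithmSpec, ClusterAssignment, run_clustering
from .preprocess import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "subsample_rows",
    "connectivity_matrix",
    "indicator_matrix",
    "consensus_cluster",
]


@dataclass
class ConsensusResult:
    """Consensus matrix plus resampling provenance.

    ``matrix`` is symmetric with off-diagonal entries in [0, 1] and unit
    diagonal.  ``never_cosampled`` flags pairs whose indicator sum is zero
    (no iteration drew both features): those entries are reported as 0, which
    scores absence of evidence as no support; raise ``iterations`` or
    ``proportion`` to shrink this set.  ``assignments`` holds the
    per-iteration (sampled ids, ClusterAssignment) pairs when retention was
    requested.
    """

    matrix: np.ndarray
    feature_ids: list[str]
    reference: ClusterAssignment
    algorithm: AlgorithmSpec
    k: int
    iterations: int
    proportion: float
    seed: int
    connectivity_sum: np.ndarray
    indicator_sum: np.ndarray
    never_cosampled: np.ndarray
    assignments: list[tuple[list[str], ClusterAssignment]] | None = field(
        default=None, repr=False
    )

    @property
    def source(self) -> str:
        return f"{self.algorithm.label()}:k={self.k}"


def _iteration_seed(master: int, index: int) -> int:
    """Deterministic per-iteration seed; independent of execution order."""
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0]
               % (2**31))


def subsample_rows(data: ExpressionMatrix, proportion: float,
                   rng: np.random.Generator) -> tuple[ExpressionMatrix, list[str]]:
    """Draw ``round(proportion · N)`` distinct rows without replacement.

    Selected rows keep their original relative order, so ``proportion=1.0``
    returns the full matrix unchanged.
    """
    if not (0 < proportion <= 1):
        raise ValueError(f"proportion must lie in (0, 1], got {proportion}")
    n = data.n_features
    size = int(round(proportion * n))
    if size < 1:
        raise ValueError(f"proportion {proportion} selects no rows from {n}")
    indices = np.sort(rng.choice(n, size=size, replace=False))
    subset = data.subset_rows(indices)
    return subset, list(subset.feature_ids)


def _positions(ids, universe: list[str]) -> np.ndarray:
    lookup = {f: i for i, f in enumerate(universe)}
    try:
        return np.array([lookup[f] for f in ids], dtype=int)
    except KeyError as exc:
        raise ValueError(f"feature id {exc.args[0]!r} not in the universe") from exc


def connectivity_matrix(assignment: ClusterAssignment,
                        universe: list[str]) -> np.ndarray:
    """Binary co-clustering matrix over ``universe``.

    Entry (i, j) is 1 iff both features were sampled *and* share a cluster;
    the diagonal is 1 for sampled features and 0 for unsampled ones.
    """
    n = len(universe)
    conn = np.zeros((n, n), dtype=np.int64)
    for members in assignment.cluster_index_sets.values():
        pos = _positions(members, universe)
        conn[np.ix_(pos, pos)] = 1
    return conn


def indicator_matrix(sampled_ids, universe: list[str]) -> np.ndarray:
    """Binary co-sampling matrix: (i, j) = 1 iff both features were drawn."""
    n = len(universe)
    ind = np.zeros((n, n), dtype=np.int64)
    pos = _positions(sampled_ids, universe)
    ind[np.ix_(pos, pos)] = 1
    return ind


def consensus_cluster(
    data: ExpressionMatrix,
    spec: AlgorithmSpec,
    k: int,
    iterations: int = 100,
    proportion: float = 0.8,
    seed: int = 0,
    keep_assignments: bool = False,
    max_retries: int = 10,
) -> ConsensusResult:
    """Run the full resampling scheme and return the consensus matrix.

    Per-iteration seeds are derived from ``(seed, iteration index)``, so the
    result is identical regardless of execution order.  The reference
    partition is obtained by clustering the complete data under the same
    ``(spec, k)``.  An iteration whose subsample defeats the backend is
    retried with a fresh draw up to ``max_retries`` times before aborting.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be positive, got {iterations}")
    n = data.n_features
    size = int(round(proportion * n))
    if size < k:
        raise ValueError(
            f"proportion {proportion} yields {size} rows, fewer than k={k}"
        )
    universe = list(data.feature_ids)
    conn_sum = np.zeros((n, n), dtype=np.int64)
    ind_sum = np.zeros((n, n), dtype=np.int64)
    kept: list[tuple[list[str], ClusterAssignment]] | None = (
        [] if keep_assignments else None
    )

    reference = run_clustering(data, k, spec, seed=_iteration_seed(seed, 0))

    for it in range(1, iterations + 1):
        last_error: Exception | None = None
        for attempt in range(max_retries + 1):
            it_seed = _iteration_seed(seed, it * (max_retries + 1) + attempt)
            rng = np.random.default_rng(it_seed)
            subset, sampled = subsample_rows(data, proportion, rng)
            try:
                assignment = run_clustering(subset, k, spec, seed=it_seed)
            except Exception as exc:  # retry with a fresh draw
                last_error = exc
                continue
            break
        else:
            raise RuntimeError(
                f"iteration {it} failed after {max_retries} retries: {last_error}"
            )
        conn_sum += connectivity_matrix(assignment, universe)
        ind_sum += indicator_matrix(sampled, universe)
        if kept is not None:
            kept.append((sampled, assignment))

    matrix = np.divide(
        conn_sum, ind_sum, out=np.zeros((n, n), dtype=float), where=ind_sum > 0
    )
    never = ind_sum == 0
    np.fill_diagonal(never, False)
    np.fill_diagonal(matrix, 1.0)
    return ConsensusResult(
        matrix=matrix,
        feature_ids=universe,
        reference=reference,
        algorithm=spec,
        k=k,
        iterations=iterations,
        proportion=proportion,
        seed=seed,
        connectivity_sum=conn_sum,
        indicator_sum=ind_sum,
        never_cosampled=never,
        assignments=kept,
    )
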