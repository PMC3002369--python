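"""Weighted merging of consensus matrices across algorithms or conditions.

Consensus matrices obtained under different clustering algorithms (or the
same algorithm under different conditions) at the *same* cluster number k are
combined by elementwise weighted averaging.  The merge blends the different
failure modes of the contributing algorithms — e.g. the outlier sensitivity
of agglomerative hierarchical methods against the outlier tolerance of
k-medoids — and, being a convex combination, remains a valid consensus-type
matrix.  Merging across different k values is refused: the matrices would
describe incomparable partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .resampling import ConsensusResult

__all__ = ["MergeResult", "merge_consensus"]


@dataclass
class MergeResult:
    """Merged consensus matrix plus its sources and normalized weights."""

    matrix: np.ndarray
    feature_ids: list[str]
    sources: list[str]
    weights: np.ndarray
    k: int
    never_cosampled: np.ndarray

    @property
    def source(self) -> str:
        return f"merge:k={self.k}"


def merge_consensus(sources: Sequence[ConsensusResult],
                    weights: Sequence[float] | None = None) -> MergeResult:
    """Elementwise weighted mean of consensus matrices sharing axes and k.

    Weights default to equal; user weights must lie in [0, 1] and not all be
    zero, and are normalized internally to sum to 1 so the result is a
    weighted mean on whatever scale the user supplied.  A pair's
    never-co-sampled flag survives only if *every* source flagged it — the
    merge exists precisely to pool evidence.
    """
    if len(sources) < 2:
        raise ValueError("merging requires at least two consensus results")
    first = sources[0]
    for s in sources[1:]:
        if s.k != first.k:
            raise ValueError(
                f"cannot merge across cluster numbers (k={first.k} vs k={s.k})"
            )
        if list(s.feature_ids) != list(first.feature_ids):
            raise ValueError("sources must share identical feature ids in order")
    if weights is None:
        w = np.full(len(sources), 1.0 / len(sources))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(sources),):
            raise ValueError(
                f"{len(sources)} sources but {w.size} weights"
            )
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        total = w.sum()
        if total == 0:
            raise ValueError("weights must not all be zero")
        w = w / total
    stack = np.stack([np.asarray(s.matrix, dtype=float) for s in sources])
    merged = np.einsum("s,sij->ij", w, stack)
    merged = (merged + merged.T) / 2  # guard against asymmetric rounding
    np.fill_diagonal(merged, 1.0)
    never = np.logical_and.reduce([s.never_cosampled for s in sources])
    return MergeResult(
        matrix=merged,
        feature_ids=list(first.feature_ids),
        sources=[s.source for s in sources],
        weights=w,
        k=first.k,
        never_cosampled=never,
    )
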