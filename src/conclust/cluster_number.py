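"""Cluster-number estimation from consensus matrices via the CDF/AUC/ΔK route.

A perfectly consistent clustering yields a consensus matrix whose
off-diagonal entries are all 0 or 1.  The empirical CDF of the off-diagonal
consensus values,

    CDF(c) = Σ_{i<j} 1{ℳ(i,j) ≤ c} / (N(N−1)/2),

then jumps from the fraction of never-co-clustered pairs straight to 1, and
its stepwise integral over the distinct sorted values x_1 < … < x_m,

    AUC = Σ_{i=2..m} (x_i − x_{i−1}) · CDF(x_i),

equals 1.  Sweeping the candidate cluster number k and tracking the change
ΔK in AUC locates the k at which consensus improves most: the ΔK peak
estimates the true cluster number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CdfCurve",
    "DeltaKProfile",
    "KEstimate",
    "consensus_cdf",
    "auc",
    "delta_k",
    "estimate_k",
]


@dataclass
class CdfCurve:
    """Empirical CDF of the off-diagonal consensus values.

    ``values`` are the ascending distinct entries x_1..x_m; ``cdf`` holds
    CDF(x_i); ``n_pairs`` is the N(N−1)/2 normaliser.
    """

    values: np.ndarray
    cdf: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cdf = np.asarray(self.cdf, dtype=float)
        if self.values.shape != self.cdf.shape:
            raise ValueError("values and cdf must align")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("values must be strictly ascending")
        if np.any(np.diff(self.cdf) < 0) or (self.cdf.size and self.cdf[-1] != 1.0):
            raise ValueError("cdf must be nondecreasing and end at 1")


@dataclass
class DeltaKProfile:
    """AUC(k) and ΔK(k) across a sweep of candidate cluster numbers."""

    k_values: list[int]
    auc: np.ndarray
    delta_k: np.ndarray
    definition: str
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "auc": self.auc, "delta_k": self.delta_k,
             "definition": self.definition, "source": self.source}
        )


class KEstimate(NamedTuple):
    """Estimated cluster number; ``k`` is None when no peak exists."""

    k: int | None
    flag: str | None = None


def consensus_cdf(matrix) -> CdfCurve:
    """Empirical CDF over the i<j entries of a consensus-type matrix."""
    m = np.asarray(getattr(matrix, "matrix", matrix), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("consensus matrix must be square")
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two features for a consensus CDF")
    if not np.allclose(m, m.T):
        raise ValueError("consensus matrix must be symmetric")
    entries = m[np.triu_indices(n, k=1)]
    if entries.min() < 0 or entries.max() > 1:
        raise ValueError("consensus entries must lie in [0, 1]")
    values, counts = np.unique(entries, return_counts=True)
    n_pairs = n * (n - 1) // 2
    return CdfCurve(values, np.cumsum(counts) / n_pairs, n_pairs)


def auc(curve: CdfCurve) -> float:
    """Stepwise integral of the consensus CDF over its distinct values.

    A single-valued curve (m = 1) has an empty sum and returns 0.0 — a
    degenerate case worth flagging upstream (every pair shares one consensus
    value, so the sweep carries no information at this k).
    """
    if curve.values.size < 2:
        return 0.0
    return float(np.sum(np.diff(curve.values) * curve.cdf[1:]))


def delta_k(auc_by_k: Mapping[int, float], definition: str = "relative",
            source: str = "") -> DeltaKProfile:
    """Change in AUC as the candidate cluster number varies.

    ``definition="relative"`` (the convention of the consensus-clustering
    literature): ΔK(k_min) = AUC(k_min) and ΔK(k) = (AUC(k) − AUC(k−1)) /
    AUC(k−1) for larger k.  ``definition="difference"``: ΔK(k) = AUC(k) −
    AUC(k−1), undefined at k_min.  A zero AUC(k−1) under "relative" makes
    that entry NaN.  Non-contiguous k grids are allowed with a warning; ΔK is
    then taken between adjacent evaluated points.
    """
    if definition not in ("relative", "difference"):
        raise ValueError(f"unknown delta-K definition {definition!r}")
    ks = sorted(int(k) for k in auc_by_k)
    if len(ks) < 2:
        raise ValueError("need at least two k values for a delta-K profile")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        warnings.warn(
            "non-contiguous k grid: delta-K computed between adjacent "
            "evaluated points", stacklevel=2,
        )
    aucs = np.array([float(auc_by_k[k]) for k in ks])
    deltas = np.empty(len(ks))
    if definition == "relative":
        deltas[0] = aucs[0]
        prev = aucs[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            deltas[1:] = np.where(prev > 0, (aucs[1:] - prev) / prev, np.nan)
    else:
        deltas[0] = np.nan
        deltas[1:] = np.diff(aucs)
    return DeltaKProfile(ks, aucs, deltas, definition, source)


def estimate_k(profile: DeltaKProfile) -> KEstimate:
    """k at the global ΔK maximum; ties break toward the smaller k.

    The seed entry at k_min (ΔK(k_min) = AUC(k_min) under "relative",
    undefined under "difference") is not a change and is excluded from the
    argmax.  A flat profile falls back to the smallest candidate k with a
    "flat" flag; a profile with no finite candidate yields no estimate.
    """
    ks = profile.k_values[1:]
    deltas = profile.delta_k[1:]
    finite = np.isfinite(deltas)
    if not finite.any():
        return KEstimate(None, "no-estimate")
    vals = deltas[finite]
    cand = [k for k, f in zip(ks, finite) if f]
    if np.ptp(vals) == 0:
        return KEstimate(cand[0], "flat")
    return KEstimate(cand[int(np.argmax(vals))], None)
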