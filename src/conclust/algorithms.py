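"""Pluggable clustering backends behind one deterministic-output contract.

The resampling engine is algorithm-agnostic: any callable that maps
``(ExpressionMatrix, k, AlgorithmSpec, seed)`` to a :class:`ClusterAssignment`
can be registered by name and driven through the consensus machinery.  Three
families are built in, covering the approaches most used for expression
profile discovery:

``hierarchical``
    Agglomerative hierarchical clustering (scipy linkage), average linkage by
    default, with complete/single/ward selectable; the tree is cut at the
    height yielding ``k`` groups.
``kmeans``
    Lloyd k-means (scikit-learn) by default; the MacQueen online-update
    variant is selectable via ``extra_params={"variant": "macqueen"}``.
``kmedoids``
    Classical PAM (partitioning around medoids) with the BUILD + SWAP
    phases; deterministic and comparatively insensitive to outliers.

Divisive hierarchical clustering and affinity propagation are not built in;
they are natural registry extensions (wrap the external implementation in a
runner and call :func:`register_algorithm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .preprocess import ExpressionMatrix

__all__ = [
    "AlgorithmSpec",
    "ClusterAssignment",
    "register_algorithm",
    "unregister_algorithm",
    "registered_algorithms",
    "run_clustering",
    "BUILTIN_ALGORITHMS",
]

#: metrics accepted by the built-in backends ("precomputed" means the input
#: matrix is itself a square dissimilarity matrix)
SUPPORTED_METRICS = frozenset(
    {"euclidean", "sqeuclidean", "cityblock", "correlation", "cosine",
     "chebyshev", "precomputed"}
)
SUPPORTED_LINKAGES = frozenset({"average", "complete", "single", "ward"})


@dataclass(frozen=True)
class AlgorithmSpec:
    """Description of a clustering backend and its parameters.

    Attributes
    ----------
    name : str
        Registry name of the backend.
    distance : str
        Distance metric ("euclidean" default; "precomputed" feeds a square
        dissimilarity matrix straight to distance-based backends).
    linkage : str or None
        Linkage criterion, hierarchical methods only (default "average").
    extra_params : mapping
        Open backend-specific options (e.g. ``{"variant": "macqueen"}``).
    seed_policy : str
        "derived" (default): the backend consumes the per-call seed;
        "ignored": the backend is deterministic and discards it.
    """

    name: str
    distance: str = "euclidean"
    linkage: str | None = None
    extra_params: Mapping = field(default_factory=dict)
    seed_policy: str = "derived"

    def __post_init__(self) -> None:
        if self.distance not in SUPPORTED_METRICS:
            raise ValueError(
                f"unsupported distance {self.distance!r}; "
                f"choose one of {sorted(SUPPORTED_METRICS)}"
            )
        if self.linkage is not None and self.linkage not in SUPPORTED_LINKAGES:
            raise ValueError(
                f"unsupported linkage {self.linkage!r}; "
                f"choose one of {sorted(SUPPORTED_LINKAGES)}"
            )

    def label(self) -> str:
        """Short human-readable identifier used in reports and plots."""
        parts = [self.name]
        if self.linkage:
            parts.append(self.linkage)
        variant = self.extra_params.get("variant") if self.extra_params else None
        if variant:
            parts.append(str(variant))
        return "-".join(parts)


@dataclass
class ClusterAssignment:
    """A discrete labelling of features into (at most) ``k`` clusters.

    ``labels`` maps every feature id to a cluster index in ``1..k``.  Labels
    are canonicalised by order of first appearance in row order, so identical
    partitions always carry identical labels.  A backend may return fewer than
    ``k`` non-empty clusters; this is recorded (``n_clusters``) rather than
    silently repaired.
    """

    labels: dict[str, int]
    k: int
    algorithm: AlgorithmSpec

    def __post_init__(self) -> None:
        for fid, lab in self.labels.items():
            if not (1 <= int(lab) <= self.k):
                raise ValueError(
                    f"label {lab} of feature {fid!r} outside 1..{self.k}"
                )
        self.labels = {str(f): int(l) for f, l in self.labels.items()}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def cluster_index_sets(self) -> dict[int, set[str]]:
        """Map cluster index -> set of member feature ids (the index sets I_k)."""
        sets: dict[int, set[str]] = {}
        for fid, lab in self.labels.items():
            sets.setdefault(lab, set()).add(fid)
        return sets

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return {c: len(m) for c, m in self.cluster_index_sets.items()}

    @property
    def n_clusters(self) -> int:
        """Number of non-empty clusters actually produced (≤ k)."""
        return len(set(self.labels.values()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"feature_id": list(self.labels), "cluster": list(self.labels.values())}
        )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

Runner = Callable[[ExpressionMatrix, int, AlgorithmSpec, int], ClusterAssignment]

_REGISTRY: dict[str, Runner] = {}


def register_algorithm(name: str, runner: Runner, *, overwrite: bool = False) -> str:
    """Register a clustering backend under ``name``.

    The runner must accept ``(data, k, spec, seed)`` and return a
    :class:`ClusterAssignment` labelling every row of ``data``.  Contract
    violations are detected at first use, not at registration.
    """
    if not name or not str(name).isidentifier():
        raise ValueError(f"algorithm name must be an identifier, got {name!r}")
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"algorithm {name!r} is already registered")
    _REGISTRY[name] = runner
    return name


def unregister_algorithm(name: str) -> None:
    _REGISTRY.pop(name, None)


def registered_algorithms() -> list[str]:
    return sorted(_REGISTRY)


def _canonicalise(raw_labels: np.ndarray, feature_ids: list[str], k: int,
                  spec: AlgorithmSpec) -> ClusterAssignment:
    """Relabel clusters 1..k by order of first appearance in row order."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return ClusterAssignment(dict(zip(feature_ids, out.tolist())), k, spec)


def run_clustering(data: ExpressionMatrix, k: int, spec: AlgorithmSpec,
                   seed: int = 0) -> ClusterAssignment:
    """Cluster ``data`` into ``k`` groups with the named backend.

    Deterministic: identical ``(data, k, spec, seed)`` always yield identical
    labels.  The returned assignment covers exactly the input's feature ids
    and carries canonical labels (first appearance in row order).
    """
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown algorithm {spec.name!r}; registered: {registered_algorithms()}"
        )
    n = data.n_features
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    result = _REGISTRY[spec.name](data, k, spec, int(seed))
    if not isinstance(result, ClusterAssignment):
        raise TypeError(
            f"runner {spec.name!r} violated the contract: returned "
            f"{type(result).__name__}, expected ClusterAssignment"
        )
    if set(result.labels) != set(data.feature_ids):
        missing = set(data.feature_ids) - set(result.labels)
        extra = set(result.labels) - set(data.feature_ids)
        raise ValueError(
            f"runner {spec.name!r} violated the contract: labels do not cover "
            f"the input rows (missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
        )
    raw = np.array([result.labels[f] for f in data.feature_ids])
    return _canonicalise(raw, list(data.feature_ids), k, spec)


# ---------------------------------------------------------------------------
# built-in backends
# ---------------------------------------------------------------------------


def _pairwise(data: ExpressionMatrix, spec: AlgorithmSpec) -> np.ndarray:
    """Condensed distance vector for distance-based backends."""
    if spec.distance == "precomputed":
        m = data.values
        if m.shape[0] != m.shape[1]:
            raise ValueError("precomputed distance requires a square matrix")
        return squareform(m, checks=False)
    return pdist(data.values, metric=spec.distance)


def _hierarchical_runner(data: ExpressionMatrix, k: int, spec: AlgorithmSpec,
                         seed: int) -> ClusterAssignment:
    method = spec.linkage or "average"
    z = linkage(_pairwise(data, spec), method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    return _canonicalise(raw, list(data.feature_ids), k, spec)


def _macqueen_kmeans(x: np.ndarray, k: int, rng: np.random.Generator,
                     max_passes: int = 50) -> np.ndarray:
    """k-means with the MacQueen online update.

    Centroids start at k distinct rows; each point is then visited in row
    order, reassigned to its nearest centroid, and the affected centroids are
    updated incrementally after every single reassignment (unlike the Lloyd
    batch update).  Passes repeat until no assignment changes.
    """
    n = x.shape[0]
    centres = x[rng.choice(n, size=k, replace=False)].astype(float)
    counts = np.zeros(k)
    labels = np.full(n, -1, dtype=int)
    for _ in range(max_passes):
        changed = False
        for i in range(n):
            d = ((centres - x[i]) ** 2).sum(axis=1)
            j = int(np.argmin(d))  # argmin breaks ties toward the lowest index
            if labels[i] == j:
                continue
            old = labels[i]
            if old >= 0 and counts[old] > 1:
                centres[old] = (centres[old] * counts[old] - x[i]) / (counts[old] - 1)
                counts[old] -= 1
            elif old >= 0:
                counts[old] -= 1  # centre of an emptied cluster stays put
            centres[j] = (centres[j] * counts[j] + x[i]) / (counts[j] + 1)
            counts[j] += 1
            labels[i] = j
            changed = True
        if not changed:
            break
    return labels + 1


def _kmeans_runner(data: ExpressionMatrix, k: int, spec: AlgorithmSpec,
                   seed: int) -> ClusterAssignment:
    if spec.distance not in ("euclidean", "sqeuclidean"):
        raise ValueError("k-means minimises squared Euclidean distance; "
                         f"distance {spec.distance!r} is not supported")
    variant = (spec.extra_params or {}).get("variant", "lloyd")
    if variant == "macqueen":
        rng = np.random.default_rng(seed)
        raw = _macqueen_kmeans(data.values, k, rng)
    elif variant == "lloyd":
        n_init = int((spec.extra_params or {}).get("n_init", 10))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31))
        raw = km.fit_predict(data.values) + 1
    else:
        raise ValueError(f"unknown k-means variant {variant!r}")
    return _canonicalise(raw, list(data.feature_ids), k, spec)


def _pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Classical PAM: greedy BUILD then steepest-descent SWAP.

    Deterministic — ties in medoid choice and in point assignment are broken
    toward the lowest index.  Returns 1-based labels.
    """
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        gains = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(medoids)
    for _ in range(200):  # SWAP passes; small k·n² each, converges quickly
        d = dist[:, medoids_arr]
        order = np.argsort(d, axis=1, kind="stable")
        idx = np.arange(n)
        nearest = order[:, 0]
        d1 = d[idx, nearest]
        d2 = d[idx, order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            mine = nearest == mi
            delta = np.where(
                mine[:, None],
                np.minimum(dist, d2[:, None]) - d1[:, None],
                np.minimum(dist - d1[:, None], 0.0),
            ).sum(axis=0)
            delta[medoids_arr] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = delta[h], (mi, h)
        if best_swap is None:
            break
        medoids_arr[best_swap[0]] = best_swap[1]
    return np.argmin(dist[:, medoids_arr], axis=1) + 1


def _kmedoids_runner(data: ExpressionMatrix, k: int, spec: AlgorithmSpec,
                     seed: int) -> ClusterAssignment:
    dist = squareform(_pairwise(data, spec), checks=False)
    raw = _pam(dist, k)
    return _canonicalise(raw, list(data.feature_ids), k, spec)


BUILTIN_ALGORITHMS = ("hierarchical", "kmeans", "kmedoids")

register_algorithm("hierarchical", _hierarchical_runner)
register_algorithm("kmeans", _kmeans_runner)
register_algorithm("kmedoids", _kmedoids_runner)
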