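"""Expression-matrix container and the preparation steps applied before consensus runs.

The container is a labelled numeric features × conditions matrix (genes or
probe-sets in rows, time points or patients in columns).  The operations here
cover the standard preparation pipeline for profile-shape clustering:
top-variance feature selection, row unitisation, transposition (for clustering
conditions instead of features), and conversion of a consensus matrix into a
dissimilarity matrix for re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "variance_filter",
    "unitise",
    "transpose",
    "consensus_to_distance",
]


@dataclass
class ExpressionMatrix:
    """Labelled numeric feature × condition matrix.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_conditions)
        Expression values; units are arbitrary but must be finite.
    feature_ids : list of str
        Unique row identifiers (e.g. gene ids).
    condition_ids : list of str
        Unique column identifiers (e.g. time points, patient ids).
    """

    values: np.ndarray
    feature_ids: list[str]
    condition_ids: list[str]
    zero_rows: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must form a 2-D matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        n, m = self.values.shape
        if len(self.feature_ids) != n:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {n} rows")
        if len(self.condition_ids) != m:
            raise ValueError(f"{len(self.condition_ids)} condition ids for {m} columns")
        for axis, ids in (("feature", self.feature_ids), ("condition", self.condition_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {axis} identifier: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at row "
                f"{self.feature_ids[bad[0]]!r}, column {self.condition_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.feature_ids),
                            columns=list(self.condition_ids))

    def subset_rows(self, indices: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the given row positions (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[indices],
            [self.feature_ids[i] for i in indices],
            list(self.condition_ids),
        )


def variance_filter(data: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` rows with highest sample variance across conditions.

    The original relative row order is preserved.  Ties at the n-th rank are
    broken by row order (earlier rows win), which makes the selection
    deterministic.
    """
    if n < 1 or n > data.n_features:
        raise ValueError(f"n must be in [1, {data.n_features}], got {n}")
    variances = np.var(data.values, axis=1, ddof=1)
    # stable argsort on descending variance keeps row order among ties
    ranked = np.argsort(-variances, kind="stable")[:n]
    return data.subset_rows(np.sort(ranked))


def unitise(data: ExpressionMatrix, variant: str = "l2") -> ExpressionMatrix:
    """Rescale each row so clustering reflects profile shape, not magnitude.

    ``variant="l2"`` (default) scales every row to unit Euclidean norm;
    ``variant="zscore"`` centres each row to mean 0 and scales to unit
    standard deviation.  Rows that cannot be scaled (all-zero under "l2",
    constant under "zscore") are left unchanged and listed in the result's
    ``zero_rows`` attribute rather than raising.
    """
    values = data.values.copy()
    flagged: list[str] = []
    if variant == "l2":
        norms = np.linalg.norm(values, axis=1)
        degenerate = norms == 0
        norms[degenerate] = 1.0
        values = values / norms[:, None]
    elif variant == "zscore":
        means = values.mean(axis=1, keepdims=True)
        sds = values.std(axis=1, ddof=1, keepdims=True)
        degenerate = (sds == 0).ravel()
        sds[degenerate] = 1.0
        values = (values - means) / sds
    else:
        raise ValueError(f"unknown unitisation variant {variant!r}")
    flagged = [data.feature_ids[i] for i in np.flatnonzero(degenerate)]
    out = ExpressionMatrix(values, list(data.feature_ids), list(data.condition_ids))
    out.zero_rows = flagged
    return out


def transpose(data: ExpressionMatrix) -> ExpressionMatrix:
    """Swap features and conditions (e.g. to cluster patients instead of genes)."""
    return ExpressionMatrix(data.values.T.copy(), list(data.condition_ids),
                            list(data.feature_ids))


def consensus_to_distance(matrix) -> np.ndarray:
    """Convert a consensus-type matrix into a dissimilarity matrix D = 1 − M.

    Pairs that always co-cluster (consensus 1) get distance 0, pairs that never
    co-cluster get distance 1.  The diagonal is forced to zero.  Accepts a raw
    square array or any object with a ``matrix`` attribute (consensus or merge
    results).
    """
    m = np.asarray(getattr(matrix, "matrix", matrix), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("consensus matrix must be symmetric")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("consensus entries must lie in [0, 1]")
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    return d
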