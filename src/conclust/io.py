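"""Delimited-text I/O for expression matrices, consensus matrices and reports.

All artefacts are plain text: matrices travel as TSV with an identifier
header row and column, and each consensus/merge matrix gets a YAML sidecar
(``<path>.meta.yaml``) recording the provenance needed to reproduce it
(algorithm, k, iterations, proportion, seed, sources, weights).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .merge import MergeResult
from .preprocess import ExpressionMatrix
from .resampling import ConsensusResult

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_consensus",
    "read_consensus",
    "write_robustness",
    "write_deltak",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Parse a delimited matrix (header row, first column = feature ids).

    The delimiter is auto-detected between tab and comma unless forced.
    Duplicate identifiers, non-numeric cells and ragged rows raise parse
    errors naming the offending row or column.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature identifier: {dup[0]!r}")
    dup_c = frame.columns[frame.columns.duplicated()]
    if len(dup_c):
        raise ValueError(f"duplicate condition identifier: {dup_c[0]!r}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value at row {bad[0]!r}, column {col!r}: "
                f"{frame.loc[bad[0], col]!r}"
            )
        frame[col] = converted
    if frame.isna().any().any():
        row, col = next(
            (r, c) for r in frame.index for c in frame.columns
            if pd.isna(frame.loc[r, c])
        )
        raise ValueError(f"missing value at row {row!r}, column {col!r}")
    return ExpressionMatrix.from_dataframe(frame)


def write_expression_matrix(data: ExpressionMatrix, path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.to_dataframe().to_csv(path, sep=sep, index_label="feature_id")
    return path


def _matrix_frame(result) -> pd.DataFrame:
    return pd.DataFrame(result.matrix, index=result.feature_ids,
                        columns=result.feature_ids)


def write_consensus(result: ConsensusResult | MergeResult, path) -> Path:
    """Write a consensus-type matrix as TSV plus a YAML provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _matrix_frame(result).to_csv(path, sep="\t", index_label="feature_id")
    if isinstance(result, MergeResult):
        meta = {
            "kind": "merge",
            "k": result.k,
            "sources": list(result.sources),
            "weights": [float(w) for w in result.weights],
        }
    else:
        meta = {
            "kind": "consensus",
            "algorithm": result.algorithm.label(),
            "distance": result.algorithm.distance,
            "k": result.k,
            "iterations": result.iterations,
            "proportion": result.proportion,
            "seed": result.seed,
        }
    with open(path.with_name(path.name + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_consensus(path) -> tuple[pd.DataFrame, dict]:
    """Load a consensus-type matrix TSV and its sidecar metadata (if present)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("consensus matrix rows and columns must carry "
                         "identical identifiers")
    values = frame.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("consensus matrix file is not symmetric")
    meta_path = path.with_name(path.name + ".meta.yaml")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return frame, meta


def write_robustness(report, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_deltak(profiles, path) -> Path:
    """Write one or more ΔK profiles as a single tidy TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not isinstance(profiles, (list, tuple)):
        profiles = [profiles]
    frames = [p.to_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path
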