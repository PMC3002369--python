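"""Experiment orchestration: the full consensus-clustering analysis run.

A run takes an expression matrix through optional preprocessing, then the
full factorial of algorithms × candidate cluster numbers, merging per-k
consensus matrices when several algorithms are configured, scoring
robustness (each consensus against its own reference, and each merge against
every source's reference), and sweeping ΔK per algorithm and for the merge.
Everything needed to reproduce a bundle — configuration, seeds,
preprocessing switches — is serialized alongside the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .algorithms import AlgorithmSpec
from .cluster_number import DeltaKProfile, KEstimate, consensus_cdf, auc, delta_k, estimate_k
from .merge import MergeResult, merge_consensus
from .preprocess import ExpressionMatrix, transpose, unitise, variance_filter
from .resampling import ConsensusResult, consensus_cluster
from .robustness import RobustnessReport, robustness_report

logger = logging.getLogger("conclust")

__all__ = ["RunConfig", "ExperimentBundle", "run_experiment", "default_algorithms"]


def default_algorithms() -> list[AlgorithmSpec]:
    """The three built-in backends under their default parameters."""
    return [
        AlgorithmSpec("hierarchical", linkage="average"),
        AlgorithmSpec("kmeans"),
        AlgorithmSpec("kmedoids"),
    ]


@dataclass
class RunConfig:
    """Everything defining one analysis run.

    ``k_range`` is inclusive.  ``merge_weights`` (optional) biases the per-k
    merge; equal weighting otherwise.  Preprocessing switches are applied in
    the order transpose → variance filter → unitise, mirroring the usual
    workflow (orient the matrix, drop uninformative rows, then make the
    clustering shape-driven).
    """

    algorithms: list[AlgorithmSpec] = field(default_factory=default_algorithms)
    k_range: tuple[int, int] = (2, 7)
    iterations: int = 100
    proportion: float = 0.8
    seed: int = 0
    merge_weights: list[float] | None = None
    variance_top: int | None = None
    unitise_variant: str | None = None
    do_transpose: bool = False
    deltak_definition: str = "relative"
    keep_assignments: bool = False
    input_path: str | None = None
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "input": self.input_path,
            "algorithms": [
                {"name": a.name, "distance": a.distance, "linkage": a.linkage,
                 "extra_params": dict(a.extra_params or {})}
                for a in self.algorithms
            ],
            "k_range": list(self.k_range),
            "iterations": self.iterations,
            "proportion": self.proportion,
            "seed": self.seed,
            "merge_weights": self.merge_weights,
            "variance_top": self.variance_top,
            "unitise_variant": self.unitise_variant,
            "transpose": self.do_transpose,
            "deltak_definition": self.deltak_definition,
        }


@dataclass
class ExperimentBundle:
    """All artefacts of one run, keyed by algorithm label and k."""

    data: ExpressionMatrix
    config: RunConfig
    consensus: dict[tuple[str, int], ConsensusResult] = field(default_factory=dict)
    merges: dict[int, MergeResult] = field(default_factory=dict)
    robustness: dict[tuple[str, int], RobustnessReport] = field(default_factory=dict)
    deltak: dict[str, DeltaKProfile] = field(default_factory=dict)
    estimates: dict[str, KEstimate] = field(default_factory=dict)
    errors: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors


def _cell_seed(master: int, alg_index: int, k: int) -> int:
    return int(
        np.random.SeedSequence([int(master), int(alg_index), int(k)])
        .generate_state(1)[0] % (2**31)
    )


def _preprocess(data: ExpressionMatrix, config: RunConfig) -> ExpressionMatrix:
    if config.do_transpose:
        data = transpose(data)
    if config.variance_top is not None:
        data = variance_filter(data, config.variance_top)
    if config.unitise_variant:
        data = unitise(data, config.unitise_variant)
        if data.zero_rows:
            logger.warning("unitise left %d degenerate rows unchanged: %s",
                           len(data.zero_rows), data.zero_rows[:5])
    return data


def run_experiment(data: ExpressionMatrix, config: RunConfig) -> ExperimentBundle:
    """Run the full factorial and assemble the bundle.

    Cell seeds derive from (master seed, algorithm index, k), so the bundle
    is reproducible and independent of execution order.  A failing
    (algorithm, k) cell is logged and recorded in ``bundle.errors``; the run
    continues and the bundle reports partial completion explicitly.
    """
    kmin, kmax = config.k_range
    data = _preprocess(data, config)
    if not (2 <= kmin <= kmax <= data.n_features):
        raise ValueError(
            f"k range [{kmin}, {kmax}] invalid for {data.n_features} features"
        )
    bundle = ExperimentBundle(data=data, config=config)
    labels = [a.label() for a in config.algorithms]
    if len(set(labels)) != len(labels):
        raise ValueError(f"algorithm labels must be unique, got {labels}")

    for ai, spec in enumerate(config.algorithms):
        for k in range(kmin, kmax + 1):
            try:
                result = consensus_cluster(
                    data, spec, k,
                    iterations=config.iterations,
                    proportion=config.proportion,
                    seed=_cell_seed(config.seed, ai, k),
                    keep_assignments=config.keep_assignments,
                )
            except Exception as exc:
                logger.error("cell (%s, k=%d) failed: %s", labels[ai], k, exc)
                bundle.errors[(labels[ai], k)] = str(exc)
                continue
            bundle.consensus[(labels[ai], k)] = result
            bundle.robustness[(labels[ai], k)] = robustness_report(
                result, result.reference, source=result.source
            )

    if len(config.algorithms) >= 2:
        for k in range(kmin, kmax + 1):
            sources = [bundle.consensus[(lab, k)] for lab in labels
                       if (lab, k) in bundle.consensus]
            if len(sources) < 2:
                continue
            merged = merge_consensus(sources, config.merge_weights)
            bundle.merges[k] = merged
            # cast the merge onto every source's reference structure
            for src in sources:
                key = (f"merge~{src.algorithm.label()}", k)
                bundle.robustness[key] = robustness_report(
                    merged, src.reference,
                    source=f"{merged.source}~{src.algorithm.label()}",
                )
    else:
        logger.info("single algorithm configured: no merge produced")

    for lab in labels:
        aucs = {
            k: auc(consensus_cdf(bundle.consensus[(lab, k)]))
            for k in range(kmin, kmax + 1) if (lab, k) in bundle.consensus
        }
        if len(aucs) >= 2:
            profile = delta_k(aucs, config.deltak_definition, source=lab)
            bundle.deltak[lab] = profile
            bundle.estimates[lab] = estimate_k(profile)
    if len(bundle.merges) >= 2:
        aucs = {k: auc(consensus_cdf(m)) for k, m in bundle.merges.items()}
        profile = delta_k(aucs, config.deltak_definition, source="merge")
        bundle.deltak["merge"] = profile
        bundle.estimates["merge"] = estimate_k(profile)

    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: ExperimentBundle, outdir) -> Path:
    """Serialize every bundle artefact plus the run configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_expression_matrix(bundle.data, outdir / "data.tsv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
    for (lab, k), result in bundle.consensus.items():
        cio.write_consensus(result, outdir / f"consensus_{lab}_k{k}.tsv")
        result.reference.to_frame().to_csv(
            outdir / f"reference_{lab}_k{k}.tsv", sep="\t", index=False
        )
    for k, merged in bundle.merges.items():
        cio.write_consensus(merged, outdir / f"merge_k{k}.tsv")
    for (lab, k), report in bundle.robustness.items():
        cio.write_robustness(report, outdir / f"robustness_{lab}_k{k}.tsv")
    if bundle.deltak:
        cio.write_deltak(list(bundle.deltak.values()), outdir / "deltak.tsv")
        with open(outdir / "estimates.yaml", "w") as fh:
            yaml.safe_dump(
                {src: {"k": est.k, "flag": est.flag}
                 for src, est in bundle.estimates.items()},
                fh, sort_keys=False,
            )
    if bundle.errors:
        with open(outdir / "errors.yaml", "w") as fh:
            yaml.safe_dump({f"{lab}:k={k}": msg
                            for (lab, k), msg in bundle.errors.items()}, fh)
    return outdir
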