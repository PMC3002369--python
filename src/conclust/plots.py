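"""Diagnostic figures for a consensus-clustering run.

For each clustering structure: per-cluster membership-robustness boxplots
(outliers beyond the 1.5×IQR whiskers drawn as open triangles), mean
expression profile per cluster, and a consensus-matrix heatmap ordered by
the reference partition; plus one ΔK figure overlaying every per-algorithm
trace and the merge trace.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_membership_boxplots", "plot_cluster_profiles",
           "plot_deltak", "plot_consensus_heatmap", "make_plots"]


def _outliers(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return values[(values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)]


def plot_membership_boxplots(report, path) -> Path | None:
    """One box per cluster of m_i(k); 1.5×IQR outliers as open triangles."""
    clusters = sorted(report.cluster_robustness)
    groups, kept = [], []
    for c in clusters:
        vals = np.array([v for (ci, _), v in report.membership_robustness.items()
                         if ci == c])
        if vals.size:
            groups.append(vals)
            kept.append(c)
    if not kept:
        return None
    fig, ax = plt.subplots(figsize=(1.2 * len(kept) + 2, 4))
    ax.boxplot(groups, tick_labels=[str(c) for c in kept], showfliers=False)
    for i, vals in enumerate(groups, start=1):
        out = _outliers(vals)
        if out.size:
            ax.plot([i] * out.size, out, marker="^", mfc="none", mec="black",
                    linestyle="none")
    ax.set_xlabel("cluster")
    ax.set_ylabel("membership robustness")
    ax.set_title(report.source)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_cluster_profiles(data, reference, path) -> Path:
    """Mean expression profile per cluster across conditions."""
    sets = reference.cluster_index_sets
    pos = {f: i for i, f in enumerate(data.feature_ids)}
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(data.n_conditions)
    for c in sorted(sets):
        members = [pos[f] for f in sets[c]]
        if not members:
            continue
        ax.plot(x, data.values[members].mean(axis=0), marker="o",
                label=f"cluster {c} (n={len(members)})")
    ax.set_xticks(x)
    ax.set_xticklabels(data.condition_ids)
    ax.set_xlabel("condition")
    ax.set_ylabel("mean expression")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_deltak(profiles, path) -> Path:
    """ΔK vs k, one trace per source (algorithms plus merge)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        style = {"linewidth": 2.5} if profile.source == "merge" else {}
        ax.plot(profile.k_values[1:], profile.delta_k[1:], marker="o",
                label=profile.source or "consensus", **style)
    ax.set_xlabel("cluster number k")
    ax.set_ylabel("delta-K")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_consensus_heatmap(result, path) -> Path:
    """Consensus matrix with rows/columns ordered by the reference clusters."""
    reference = getattr(result, "reference", None)
    order = np.arange(len(result.feature_ids))
    if reference is not None:
        labels = np.array([reference.labels[f] for f in result.feature_ids])
        order = np.argsort(labels, kind="stable")
    m = result.matrix[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="consensus")
    ax.set_title(getattr(result, "source", "consensus"))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def make_plots(bundle, outdir) -> list[Path]:
    """All figures for a bundle; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (lab, k), report in bundle.robustness.items():
        p = plot_membership_boxplots(report, outdir / f"box_{lab}_k{k}.png")
        if p:
            written.append(p)
    for (lab, k), result in bundle.consensus.items():
        written.append(plot_cluster_profiles(
            bundle.data, result.reference, outdir / f"profiles_{lab}_k{k}.png"))
        written.append(plot_consensus_heatmap(
            result, outdir / f"heatmap_{lab}_k{k}.png"))
    for k, merged in bundle.merges.items():
        written.append(plot_consensus_heatmap(
            merged, outdir / f"heatmap_merge_k{k}.png"))
    if bundle.deltak:
        written.append(plot_deltak(list(bundle.deltak.values()),
                                   outdir / "deltak.png"))
    return written
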