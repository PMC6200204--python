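"""Figures: silhouette panels, boundary-effect scatter, per-channel kinematics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .channels import CHANNELS
from .clustering import ClusterEnsemble
from .preprocessing import ParticipantWaveforms, mean_patterns_deg
from .selection import AlignedEnsemble, boundary_analysis
from .spm import DeviationReport
from .synthetic import NDReference, STANCE_GRID

__all__ = ["plot_silhouettes", "plot_boundary_effect", "plot_channel_kinematics",
           "plot_all"]


def plot_silhouettes(ensemble: ClusterEnsemble, path: str | Path,
                     repetition: int = 0) -> None:
    """One panel per k: sorted silhouette values, grouped by cluster."""
    ks = ensemble.k_range
    fig, axes = plt.subplots(1, len(ks), figsize=(3.2 * len(ks), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, k in zip(axes, ks):
        res = ensemble.results[(repetition, k)]
        sil = ensemble.silhouettes[(repetition, k)]
        order = np.lexsort((-sil.s_values, res.labels))
        colors = plt.cm.tab10(res.labels[order] % 10)
        ax.barh(np.arange(order.size), sil.s_values[order], color=colors)
        ax.set_title(f"k = {k} (mean s = {sil.mean_s:.3f})")
        ax.set_xlabel("silhouette value")
    axes[0].set_ylabel("participants (sorted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_boundary_effect(aligned: AlignedEnsemble, path: str | Path) -> None:
    """Allocation switches against mean silhouette per participant."""
    table = boundary_analysis(aligned)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(table["mean_s"], table["n_switches"], c=table["final_label"],
               cmap="tab10", edgecolor="k", linewidth=0.4)
    ax.set_xlabel("mean silhouette value")
    ax.set_ylabel("allocation switches across repetitions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_channel_kinematics(
    channel: str,
    clusters: dict[int, list[ParticipantWaveforms]],
    nd_reference: NDReference,
    deviations: DeviationReport,
    path: str | Path,
) -> None:
    """Cluster means vs ND mean with significant intervals shaded."""
    nd_mean = np.mean([t.base_curve for t in nd_reference[channel]], axis=0)
    cluster_ids = sorted(clusters)
    fig, axes = plt.subplots(1, len(cluster_ids),
                             figsize=(3.2 * len(cluster_ids), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, cid in zip(axes, cluster_ids):
        members = clusters[cid]
        curves = np.vstack([mean_patterns_deg(p)[channel] for p in members])
        ax.plot(STANCE_GRID, nd_mean, color="green", label="ND")
        ax.plot(STANCE_GRID, curves.mean(axis=0), color="red",
                label=f"cluster {cid}")
        spm = deviations.spm.get((cid, channel))
        if spm is not None:
            for a, b, _sign in spm.intervals:
                ax.axvspan(a, b, color="0.8", zorder=0)
        ax.set_title(f"C{cid} (n = {len(members)})")
        ax.set_xlabel("% stance")
    axes[0].set_ylabel(f"{channel} angle (deg)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_all(ensemble: ClusterEnsemble, aligned: AlignedEnsemble,
             clusters: dict[int, list[ParticipantWaveforms]],
             nd_reference: NDReference, deviations: DeviationReport,
             out_dir: str | Path) -> list[Path]:
    """The full figure set: silhouettes, boundary effect, five channel figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "silhouettes.png", out / "boundary_effect.png"]
    plot_silhouettes(ensemble, paths[0])
    plot_boundary_effect(aligned, paths[1])
    for channel in CHANNELS:
        p = out / f"kinematics_{channel}.png"
        plot_channel_kinematics(channel, clusters, nd_reference, deviations, p)
        paths.append(p)
    return paths
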