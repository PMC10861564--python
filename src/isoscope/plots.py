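"""Headless-safe plotting helpers; every number plotted also lands in tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import KMeansResult, PCAResult, TrajectoryMatrix

__all__ = ["plot_mid_timecourse", "plot_cluster_trajectories", "plot_pca"]


def plot_mid_timecourse(times_h, mids, labels, path, title=""):
    """Stacked isotopologue-fraction trajectories (one line per channel)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    mids = np.asarray(mids)
    for i, lab in enumerate(labels):
        ax.plot(times_h, mids[i], marker="o", label=lab)
    ax.set_xlabel("labeling time (h)")
    ax.set_ylabel("isotopologue fraction")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cluster_trajectories(traj: TrajectoryMatrix, km: KMeansResult, path):
    """Mean +/- SD band per cluster over the labeling time course."""
    fig, ax = plt.subplots(figsize=(6, 4))
    times = traj.times
    X = traj.as_array()
    for c in range(km.k):
        members = km.labels.to_numpy() == c
        if not members.any():
            continue
        mean = X[members].mean(axis=0)
        sd = X[members].std(axis=0)
        ax.plot(times, mean, label=f"cluster {c} (n={members.sum()})")
        ax.fill_between(times, mean - sd, mean + sd, alpha=0.25)
    ax.set_xlabel("labeling time (h)")
    ax.set_ylabel("label quantity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_pca(pca: PCAResult, km: KMeansResult, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    scores = pca.scores
    for c in sorted(km.labels.unique()):
        mask = km.labels == c
        ax.scatter(scores.loc[mask, "PC1"], scores.loc[mask, "PC2"], label=f"cluster {c}")
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]*100:.0f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]*100:.0f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
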