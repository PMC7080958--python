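"""Static figures: genome-wide frequency track and cluster heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort_clustering import ClusterAssignment
from .genome_model import BinGrid

__all__ = ["plot_frequency_profile", "plot_cna_heatmap"]


def plot_frequency_profile(profile: pd.DataFrame, grid: BinGrid, path) -> None:
    """Per-chromosome gain (red, up) / loss (blue, down) frequency track."""
    fig, ax = plt.subplots(figsize=(12, 3))
    x = np.arange(len(profile))
    ax.fill_between(x, 0, profile["gain_freq"], step="mid", color="tab:red", lw=0)
    ax.fill_between(x, 0, -profile["loss_freq"], step="mid", color="tab:blue", lw=0)
    boundaries = [grid.offsets[c] for c in grid.build.chroms[1:]]
    for b in boundaries:
        ax.axvline(b, color="0.7", lw=0.5)
    ticks = [
        grid.offsets[c] + grid.n_bins_chrom(c) / 2 for c in grid.build.chroms
    ]
    ax.set_xticks(ticks)
    ax.set_xticklabels(grid.build.chroms, fontsize=7)
    ax.set_ylim(-1, 1)
    ax.set_ylabel("loss freq    gain freq")
    ax.set_xlim(0, len(profile))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cna_heatmap(
    matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    grid: BinGrid,
    path,
    clinical: pd.DataFrame | None = None,
) -> None:
    """Bins-by-samples heatmap with samples ordered by cluster."""
    order = assignment.labels.sort_values(kind="mergesort").index
    data = matrix[order].to_numpy()
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(
        data, aspect="auto", cmap="bwr", vmin=-1, vmax=1, interpolation="nearest"
    )
    # cluster boundaries along x
    labels = assignment.labels.loc[order].to_numpy()
    for i in np.flatnonzero(labels[1:] != labels[:-1]):
        ax.axvline(i + 0.5, color="k", lw=1)
    ticks = [
        grid.offsets[c] + grid.n_bins_chrom(c) / 2 for c in grid.build.chroms
    ]
    ax.set_yticks(ticks)
    ax.set_yticklabels(grid.build.chroms, fontsize=7)
    ax.set_xlabel(f"samples (k={assignment.k} clusters)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
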