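"""Figure output: clustered correlation heatmap, motif-score heatmap and
average cut profiles.  All figures are optional pipeline artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from regnet.accessibility import hierarchical_cluster

__all__ = ["correlation_heatmap", "motif_score_heatmap", "average_profile_plot"]


def correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> None:
    """Sample-correlation heatmap with leaves in dendrogram order."""
    _, order = hierarchical_cluster(corr)
    data = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(1 + 0.45 * len(order), 1 + 0.45 * len(order)))
    im = ax.imshow(data.values, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def motif_score_heatmap(scores: pd.DataFrame, path: str | Path) -> None:
    """Motif x condition heatmap of log2 enrichment scores."""
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * scores.shape[1], 1 + 0.25 * scores.shape[0])
    )
    vmax = max(1.0, float(np.abs(scores.values).max()))
    im = ax.imshow(scores.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(scores.shape[1]), scores.columns, rotation=45,
                  fontsize=8)
    ax.set_yticks(range(scores.shape[0]), scores.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 motif score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def average_profile_plot(
    profiles_by_group: Mapping[str, Sequence[float]],
    path: str | Path,
    title: str = "average DNaseI cut profile",
) -> None:
    """Overlay per-group average cut profiles across the window."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for group, profile in profiles_by_group.items():
        profile = np.asarray(profile, dtype=float)
        x = np.arange(len(profile)) - len(profile) // 2
        ax.plot(x, profile, label=group, linewidth=1)
    ax.set_xlabel("bp from peak center")
    ax.set_ylabel("mean cuts/bp")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
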