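"""SVG figures: barcodes, persistence diagrams, dendrograms, screening plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cluster import Dendrogram
from .rips import PersistenceDiagram

_COLORS = {0: "tab:red", 1: "tab:blue", 2: "tab:green"}


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_barcode(diagram: PersistenceDiagram, path: str | Path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    y = 0
    for dim in (0, 1, 2):
        for b, d in diagram.in_dim(dim):
            ax.hlines(y, b, d, color=_COLORS[dim], lw=1.5)
            y += 1
    ax.set_xlabel("filtration value")
    ax.set_ylabel("feature")
    ax.set_title("persistence barcode (B0 red, B1 blue, B2 green)")
    fig.savefig(path)
    plt.close(fig)


def plot_diagram(diagram: PersistenceDiagram, path: str | Path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    cap = diagram.max_edge_length
    ax.plot([0, cap], [0, cap], "k--", lw=0.8)
    for dim in (0, 1, 2):
        pairs = diagram.in_dim(dim)
        if len(pairs):
            ax.scatter(pairs[:, 0], pairs[:, 1], s=18, color=_COLORS[dim], label=f"B{dim}")
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.legend()
    fig.savefig(path)
    plt.close(fig)


def plot_dendrogram(dendro: Dendrogram, path: str | Path, truncate: int | None = None) -> None:
    from scipy.cluster import hierarchy

    plt = _axes()
    fig, ax = plt.subplots(figsize=(8, 4))
    kwargs = {}
    if truncate is not None:
        kwargs = {"truncate_mode": "lastp", "p": truncate, "show_contracted": True}
    hierarchy.dendrogram(dendro.linkage, ax=ax, no_labels=True, **kwargs)
    ax.set_ylabel("Ward merge distance")
    fig.savefig(path)
    plt.close(fig)


def plot_selectivity_boxplots(cluster_stats, per_structure, path: str | Path) -> None:
    """Boxplots of the over-10 selectivities per cluster, mean as a red dot."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(7, 4))
    over = per_structure[(per_structure["selectivity"] > 10)
                         & np.isfinite(per_structure["selectivity"])]
    groups = [(cid, grp["selectivity"].to_numpy()) for cid, grp in over.groupby("cluster")]
    if groups:
        ax.boxplot([g for _, g in groups], tick_labels=[str(c) for c, _ in groups])
        ax.scatter(range(1, len(groups) + 1), [g.mean() for _, g in groups],
                   color="red", zorder=3, label="mean")
        ax.legend()
    ax.set_xlabel("cluster")
    ax.set_ylabel("Xe/Kr selectivity (> 10)")
    fig.savefig(path)
    plt.close(fig)
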