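"""Optional figures: degree-rank slope graph, category heatmap, adjacency matrix."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import ADJ_DIRECT, ADJ_FOCAL, AdjacencyReport, CategoryPairMatrix


def plot_degree_rank_slope(table: pd.DataFrame, path) -> None:
    """Slope graph of degree ranks (rank 1 on top); newly connected in black."""
    fig, ax = plt.subplots(figsize=(5, 7))
    for disease, row in table.iterrows():
        color = "black" if row["newly_connected"] else "tab:gray"
        ax.plot([0, 1], [row["rank_ssddn"], row["rank_ssddnplus"]],
                marker="o", ms=3, lw=1, color=color, alpha=0.7)
    ax.set_xticks([0, 1], ["ssDDN", "ssDDN+"])
    ax.invert_yaxis()
    ax.set_ylabel("degree rank (1 = most connected)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_category_heatmap(matrix: CategoryPairMatrix, path,
                          normalized: bool = True) -> None:
    data = matrix.normalized if normalized else matrix.raw
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(data.to_numpy(float), cmap="inferno")
    ax.set_xticks(range(len(matrix.categories)), matrix.categories,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.categories)), matrix.categories, fontsize=7)
    fig.colorbar(im, ax=ax, label="edges per node pair" if normalized else "edges")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_adjacency(report: AdjacencyReport, path) -> None:
    """Upper triangle: direct (gray) vs focal-trait (red) edges; lower: counts."""
    mat = report.matrix.to_numpy()
    n = len(report.nodes)
    colors = np.ones((n, n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] == ADJ_DIRECT:
                colors[i, j] = (0.6, 0.6, 0.6)
            elif mat[i, j] == ADJ_FOCAL:
                colors[i, j] = (0.85, 0.2, 0.2)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(colors)
    for i in range(n):
        for j in range(i):
            if mat[i, j]:
                ax.text(j, i, str(mat[i, j]), ha="center", va="center",
                        fontsize=6, color="tab:red")
    ax.set_xticks(range(n), report.nodes, rotation=90, fontsize=6)
    ax.set_yticks(range(n), report.nodes, fontsize=6)
    ax.set_title(f"edges via {report.focal_trait} (red) vs direct (gray)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
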