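"""Static visual outputs: PCA score plots, heatmaps, Ward dendrograms.

These mirror the files a manual assessment would look at; they are emitted
as non-interactive PNG/PDF artifacts only.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage

from .autocluster import ClusterResult, Embedding

__all__ = ["score_plot", "distance_heatmap", "ward_dendrogram"]


def score_plot(embedding: Embedding, result: ClusterResult, path) -> None:
    """PC1-vs-PC2 scatter colour-coded by cluster, labelled by gene id."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.array([result.assignment[g] for g in embedding.gene_ids])
    sc = ax.scatter(
        embedding.scores[:, 0], embedding.scores[:, 1],
        c=labels, cmap="tab10", s=60,
    )
    for gid, (x, y) in zip(embedding.gene_ids, embedding.scores[:, :2]):
        ax.annotate(gid, (x, y), fontsize=8, xytext=(3, 3),
                    textcoords="offset points")
    ve = embedding.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.1%})")
    ax.set_ylabel(f"PC2 ({ve[1]:.1%})")
    ax.set_title(
        f"{embedding.source} matrix — k={result.k} ({result.method})"
    )
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def distance_heatmap(matrix: np.ndarray, gene_ids: list[str], path,
                     title: str = "distance") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(matrix, dtype=float), cmap="viridis")
    ax.set_xticks(range(len(gene_ids)), gene_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(gene_ids)), gene_ids, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ward_dendrogram(matrix: np.ndarray, gene_ids: list[str], path,
                    title: str = "Ward dendrogram") -> None:
    """Ward's minimum-variance dendrogram of the matrix row profiles."""
    import warnings

    m = np.asarray(matrix, dtype=float)
    with warnings.catch_warnings():
        # rows-as-observations is intentional: we cluster distance profiles
        warnings.simplefilter("ignore")
        z = linkage(m, method="ward")
    fig, ax = plt.subplots(figsize=(7, 4))
    dendrogram(z, labels=gene_ids, ax=ax, leaf_font_size=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
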