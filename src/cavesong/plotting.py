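"""Publication-style plots: violins per group, PCA ellipse scatter,
confusion matrix, and the acoustic tree projected on cave coordinates."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .features import FeatureTable
from .signatures import AcousticSpace, GeoClustering, PDFAResult

__all__ = [
    "plot_violin",
    "plot_acoustic_space",
    "plot_confusion",
    "plot_geo_cluster",
]


def plot_violin(table: FeatureTable, feature: str,
                ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Violin plot of one acoustic parameter per group, medians marked."""
    ax = ax or plt.subplots()[1]
    groups = table.groups
    data = [table.group_values(feature)[g] for g in groups]
    ax.violinplot(data, showmedians=True, showextrema=False)
    ax.set_xticks(np.arange(1, len(groups) + 1), groups, rotation=45)
    ax.set_ylabel(feature)
    return ax


def plot_acoustic_space(space: AcousticSpace,
                        ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Scatter of events in the first two principal axes with per-group
    confidence ellipses around centroids."""
    ax = ax or plt.subplots()[1]
    cmap = plt.get_cmap("tab10")
    for i, (g, sub) in enumerate(space.scores.groupby("group", observed=True)):
        color = cmap(i % 10)
        ax.scatter(sub["pc1"], sub["pc2"], s=8, alpha=0.6, color=color,
                   label=str(g))
        if g in space.ellipses:
            b = space.ellipses[g].boundary()
            ax.plot(b[:, 0], b[:, 1], color=color, lw=1.5)
    ev = space.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.0f}%)")
    if ev.size > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.0f}%)")
    ax.legend(fontsize="small")
    return ax


def plot_confusion(result: PDFAResult,
                   ax: Optional[plt.Axes] = None) -> plt.Axes:
    """pDFA confusion matrix with per-cell reclassification percentages."""
    ax = ax or plt.subplots()[1]
    conf = result.confusion.to_numpy(float)
    frac = conf / conf.sum(axis=1, keepdims=True)
    ax.imshow(frac, cmap="Blues", vmin=0, vmax=1)
    labels = list(result.confusion.index)
    ax.set_xticks(range(len(labels)), labels, rotation=45)
    ax.set_yticks(range(len(labels)), labels)
    for i in range(len(labels)):
        for j in range(len(labels)):
            ax.text(j, i, f"{100 * frac[i, j]:.0f}", ha="center", va="center",
                    color="black" if frac[i, j] < 0.6 else "white",
                    fontsize="small")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"pDFA reclassification "
                 f"{100 * result.overall_reclassification:.0f}%, "
                 f"p = {result.p_value:.3g}")
    return ax


def _node_position(node, positions):
    if node.is_leaf():
        return positions[node.id]
    return tuple(np.mean([_node_position(node.left, positions),
                          _node_position(node.right, positions)], axis=0))


def plot_geo_cluster(geo: GeoClustering,
                     ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Acoustic clustering tree projected onto cave coordinates: leaves sit
    at (longitude, latitude); merges join midpoints."""
    from scipy.cluster.hierarchy import to_tree

    ax = ax or plt.subplots()[1]
    positions = {i: geo.group_coordinates[g] for i, g in enumerate(geo.labels)}
    tree = to_tree(geo.linkage_matrix)

    def draw(node):
        if node.is_leaf():
            return
        p = _node_position(node, positions)
        for child in (node.left, node.right):
            c = _node_position(child, positions)
            ax.plot([p[0], c[0]], [p[1], c[1]], color="gray", lw=1)
            draw(child)

    draw(tree)
    for g in geo.labels:
        lon, lat = geo.group_coordinates[g]
        ax.scatter([lon], [lat], s=30)
        ax.annotate(g, (lon, lat), textcoords="offset points", xytext=(4, 4),
                    fontsize="small")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
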