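"""Matplotlib figures for the standard outputs.

Thin wrappers: every function takes computed results and an optional Axes,
returns the Axes, and never computes statistics itself.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .ena import AXES, ENASpace, group_means_ci
from .repertoire import ClusterResult, RarefactionCurve


def plot_rarefaction(curves: list[RarefactionCurve], ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Element accumulation curves with +-1 sd bands."""
    ax = ax or plt.gca()
    for c in curves:
        ax.plot(c.x, c.mean, label=c.label)
        ax.fill_between(c.x, c.mean - c.sd, c.mean + c.sd, alpha=0.2)
    ax.set_xlabel("videos sampled")
    ax.set_ylabel("distinct behavioral elements")
    ax.legend(fontsize="small")
    return ax


def plot_repertoire_heatmap(result: ClusterResult, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Dendrogram-ordered heatmap of globally max-normalized usage."""
    ax = ax or plt.gca()
    mat = result.normalized.loc[result.leaf_order]
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize="small")
    ax.set_xlabel("technique")
    plt.colorbar(im, ax=ax, label="normalized frequency")
    return ax


def plot_dendrogram(result: ClusterResult, ax: Optional[plt.Axes] = None) -> plt.Axes:
    ax = ax or plt.gca()
    sch.dendrogram(result.linkage, labels=list(result.normalized.index), ax=ax,
                   leaf_rotation=90)
    ax.set_ylabel("merge distance")
    return ax


def plot_similarity_boxes(profiles: list, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Box plot of per-individual similarity profiles (one box per community)."""
    ax = ax or plt.gca()
    data = [p.values.to_numpy() for p in profiles]
    labels = [p.community for p in profiles]
    ax.boxplot(data, tick_labels=labels, whis=(2.5, 97.5))
    for i, v in enumerate(data, start=1):
        ax.plot(np.full(len(v), i), v, "o", alpha=0.5, ms=3)
    ax.set_ylabel("Sørensen similarity")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_ena_space(space: ENASpace, level: float = 0.95,
                   ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Projected units (circles), group means (squares) and CI boxes."""
    ax = ax or plt.gca()
    ci = group_means_ci(space, level=level)
    cmap = plt.get_cmap("tab10")
    for k, g in enumerate(ci.index):
        members = space.groups[space.groups == g].index
        pts = space.unit_points.loc[members]
        color = cmap(k % 10)
        ax.plot(pts["SVD1"], pts["SVD2"], "o", color=color, alpha=0.6, label=g)
        ax.plot(ci.loc[g, "SVD1_mean"], ci.loc[g, "SVD2_mean"], "s", color=color, ms=9)
        if np.isfinite(ci.loc[g, "SVD1_lo"]):
            x0, x1 = ci.loc[g, "SVD1_lo"], ci.loc[g, "SVD1_hi"]
            y0, y1 = ci.loc[g, "SVD2_lo"], ci.loc[g, "SVD2_hi"]
            ax.plot([x0, x1, x1, x0, x0], [y0, y0, y1, y1, y0], ":", color=color)
    ve = space.variance_explained * 100
    ax.set_xlabel(f"{AXES[0]} ({ve[0]:.1f}% variance)")
    ax.set_ylabel(f"{AXES[1]} ({ve[1]:.1f}% variance)")
    ax.legend(fontsize="small")
    return ax


def plot_network(space: ENASpace, weights: pd.Series, scale: float = 4.0,
                 ax: Optional[plt.Axes] = None) -> plt.Axes:
    """One group's mean network over the co-registered node positions."""
    if space.node_positions is None:
        raise ValueError("run position_nodes(space) before plotting networks")
    ax = ax or plt.gca()
    pos = space.node_positions
    wmax = float(weights.max()) or 1.0
    for (a, b), w in weights.items():
        if w <= 0:
            continue
        ax.plot(
            [pos.loc[a, "SVD1"], pos.loc[b, "SVD1"]],
            [pos.loc[a, "SVD2"], pos.loc[b, "SVD2"]],
            "-", color="steelblue", lw=scale * w / wmax, alpha=0.7,
        )
    ax.plot(pos["SVD1"], pos["SVD2"], "o", color="black", ms=4)
    for el, row in pos.iterrows():
        ax.annotate(el, (row["SVD1"], row["SVD2"]), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    return ax
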