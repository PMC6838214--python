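"""Frequency-polygon and ECDF plots for univariate summary distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .summaries import SummaryDistribution

__all__ = ["frequency_polygon", "ecdf_plot", "plot_univariate", "rank_boxplot", "mds_scatter"]

PLOT_STYLES = ("frequency_polygon", "ecdf")


def frequency_polygon(ax, dist: SummaryDistribution, bins: int = 30, **kwargs):
    counts, edges = np.histogram(dist.values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    ax.plot(centers, counts, **kwargs)
    ax.set_xlabel(dist.name)
    ax.set_ylabel("frequency")
    return ax


def ecdf_plot(ax, dist: SummaryDistribution, **kwargs):
    x = np.sort(dist.values)
    y = np.arange(1, x.size + 1) / x.size
    ax.step(x, y, where="post", **kwargs)
    ax.set_xlabel(dist.name)
    ax.set_ylabel("ECDF")
    return ax


def plot_univariate(
    dist: SummaryDistribution, style: str, out_base: str | Path, formats=("svg", "png")
) -> list[Path]:
    """Write one univariate distribution plot; style is one of PLOT_STYLES."""
    if style not in PLOT_STYLES:
        raise ValueError(f"style must be one of {PLOT_STYLES}")
    fig, ax = plt.subplots(figsize=(4, 3))
    (frequency_polygon if style == "frequency_polygon" else ecdf_plot)(ax, dist)
    paths = []
    for fmt in formats:
        p = Path(f"{out_base}.{fmt}")
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def rank_boxplot(per_class_ranks, out_base: str | Path, formats=("svg", "png")) -> list[Path]:
    """Boxplots of per-class ranks ordered by median (most informative first)."""
    order = per_class_ranks.median(axis=0).sort_values().index
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(order) + 1.5))
    ax.boxplot(
        [per_class_ranks[c].to_numpy() for c in order],
        vert=False, tick_labels=list(order),
    )
    ax.set_xlabel("rank across dataset classes")
    paths = []
    for fmt in formats:
        p = Path(f"{out_base}.{fmt}")
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def mds_scatter(coords, labels, out_base: str | Path, formats=("svg", "png")) -> list[Path]:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(coords[:, 0], coords[:, 1])
    for (x, y), lab in zip(coords, labels):
        ax.annotate(lab, (x, y), fontsize=7)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    paths = []
    for fmt in formats:
        p = Path(f"{out_base}.{fmt}")
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths
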