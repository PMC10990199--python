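"""Figure rendering: haplotype map, MST network, bivariate diversity plot.

These are deliberately plain matplotlib renderings (polygon-free: point
pies on a lat/lon frame), intended for quick inspection and atlas bundles,
not publication styling.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .embedding import Embedding
from .network import AreaPie, HaplotypeNetwork


def plot_network(network: HaplotypeNetwork,
                 colors: dict[str, tuple[float, float, float]],
                 path: str | Path, seed: int = 0) -> None:
    g = nx.Graph()
    counts = dict(network.nodes)
    for h, c in network.nodes:
        g.add_node(h)
    for e in network.primary_edges:
        g.add_edge(e.hap_a, e.hap_b, weight=e.steps)
    pos = nx.spring_layout(g, seed=seed, weight=None)
    fig, ax = plt.subplots(figsize=(6, 6))
    for e in network.alternative_edges:
        xa, ya = pos[e.hap_a]
        xb, yb = pos[e.hap_b]
        ax.plot([xa, xb], [ya, yb], ls="--", color="0.7", zorder=1)
    for e in network.primary_edges:
        xa, ya = pos[e.hap_a]
        xb, yb = pos[e.hap_b]
        ax.plot([xa, xb], [ya, yb], color="0.3", zorder=2)
        ax.annotate(str(e.steps), ((xa + xb) / 2, (ya + yb) / 2),
                    fontsize=7, color="0.2")
    sizes = np.array([counts[h] for h in g.nodes], dtype=float)
    ax.scatter([pos[h][0] for h in g.nodes], [pos[h][1] for h in g.nodes],
               s=60 * sizes / sizes.max() * 4,
               c=[colors.get(h, (0.5, 0.5, 0.5)) for h in g.nodes],
               edgecolors="black", zorder=3)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_haplotype_map(pies: list[AreaPie], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    max_n = max(p.n for p in pies)
    for p in pies:
        radius_pts = 8 + 20 * math.sqrt(p.n / max_n)
        total = p.n
        start = 0.0
        for hid, cnt in sorted(p.composition.items()):
            frac = cnt / total
            theta = np.linspace(2 * np.pi * start, 2 * np.pi * (start + frac), 24)
            xs = np.concatenate([[0], np.cos(theta)]) * radius_pts / 72
            ys = np.concatenate([[0], np.sin(theta)]) * radius_pts / 72
            ax.fill(p.centroid_lon + xs, p.centroid_lat + ys,
                    color=p.colors[hid], ec="black", lw=0.3)
            start += frac
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_bivariate(plot_points, medians: dict, path: str | Path,
                   highlight: str | None = None) -> None:
    """Bubble plot of sqrt(pi) against G_ST with per-axis median lines."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(plot_points["sqrt_pi"], plot_points["gst"],
               s=40, color="0.6", alpha=0.7)
    if highlight is not None and highlight in set(plot_points["species"]):
        row = plot_points[plot_points["species"] == highlight].iloc[0]
        ax.scatter([row["sqrt_pi"]], [row["gst"]], s=60, color="purple")
    if medians.get("sqrt_pi") is not None:
        ax.axvline(medians["sqrt_pi"], color="black", lw=1)
    if medians.get("gst") is not None:
        ax.axhline(medians["gst"], color="black", lw=1)
    ax.set_xlabel(r"$\sqrt{\pi}$")
    ax.set_ylabel(r"$G_{ST}$")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
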