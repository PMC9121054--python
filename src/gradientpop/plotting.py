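"""Optional figures: rarefaction violins and haplotype networks."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .resampling import RarefactionResult

POP_COLORS = {"north": "#2b5d8c", "baltic": "#c0504d", "transition": "#999999"}


def plot_rarefaction(results: Sequence[RarefactionResult], path, statistics=("phi_st", "snn")):
    """Violin plots of subsample estimates with the full-data point estimate."""
    fig, axes = plt.subplots(1, len(statistics), figsize=(4 * len(statistics), 3.2), squeeze=False)
    for ax, stat in zip(axes[0], statistics):
        rows = [r for r in results if r.statistic == stat and r.replicates]
        if not rows:
            ax.set_visible(False)
            continue
        sizes = [r.subsample_size for r in rows]
        ax.violinplot([r.replicates for r in rows], showmedians=True)
        ax.set_xticks(range(1, len(rows) + 1), [str(s) for s in sizes])
        for i, r in enumerate(rows, start=1):
            ax.plot(i, r.full_estimate, "o", color="red", zorder=3)
        ax.set_xlabel("sequences per population")
        ax.set_title(stat)
    fig.suptitle(results[0].species if results else "")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_network(G: nx.Graph, path, seed: int = 0):
    """Minimum spanning haplotype network; node area tracks counts."""
    pos = nx.spring_layout(G, seed=seed, weight=None)
    fig, ax = plt.subplots(figsize=(5, 5))
    sizes = [80 + 60 * G.nodes[n]["count"] for n in G.nodes]
    # color by majority population
    colors = []
    for n in G.nodes:
        pc = G.nodes[n].get("pop_counts", {})
        major = max(pc, key=pc.get) if pc else "north"
        colors.append(POP_COLORS.get(major, "#777777"))
    nx.draw_networkx(G, pos, ax=ax, node_size=sizes, node_color=colors,
                     with_labels=False, edge_color="#555555")
    labels = {(u, v): d["weight"] for u, v, d in G.edges(data=True)}
    nx.draw_networkx_edge_labels(G, pos, edge_labels=labels, ax=ax, font_size=7)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
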