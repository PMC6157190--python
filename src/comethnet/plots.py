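"""Figure generation: clustering dendrogram with module color bars and
side-by-side pre/post module network plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from comethnet.ghd import binarize_network
from comethnet.network import ModuleAssignment

__all__ = ["plot_dendrogram", "plot_module_network"]


def plot_dendrogram(
    linkage_matrix: np.ndarray,
    color_bars: dict[str, pd.Series],
    out_path: str | Path,
) -> Path:
    """Dendrogram with one aligned module-color bar per entry of ``color_bars``.

    Each color bar is a probe-indexed series of matplotlib color names
    (unassigned probes should already carry the reserved 'grey').
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    n_bars = len(color_bars)
    fig, axes = plt.subplots(
        1 + n_bars,
        1,
        figsize=(10, 5 + 0.4 * n_bars),
        gridspec_kw={"height_ratios": [5] + [0.4] * n_bars},
        sharex=False,
    )
    axes = np.atleast_1d(axes)
    dend = dendrogram(linkage_matrix, ax=axes[0], no_labels=True, color_threshold=0)
    order = dend["leaves"]
    axes[0].set_ylabel("1 - TOM")
    for ax, (name, colors) in zip(axes[1:], color_bars.items()):
        ordered = colors.iloc[order]
        for i, c in enumerate(ordered):
            ax.add_patch(plt.Rectangle((i, 0), 1, 1, color=c, linewidth=0))
        ax.set_xlim(0, len(ordered))
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_xticks([])
        ax.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_module_network(
    pre_cor: pd.DataFrame,
    post_cor: pd.DataFrame,
    modules: ModuleAssignment,
    module: int,
    tau: float = 0.2,
    out_path: str | Path = "module_network.png",
) -> Path:
    """Side-by-side pre/post node-edge plots of one module.

    Edges are drawn where the binarized |correlation| adjacency is 1; both
    panels share a layout computed on the union graph so structural change
    is visible directly.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    probes = list(modules.module_probes(module))
    if not probes:
        raise ValueError(f"module {module} has no probes")
    pre_adj = binarize_network(pre_cor.loc[probes, probes], tau).to_numpy()
    post_adj = binarize_network(post_cor.loc[probes, probes], tau).to_numpy()
    g_pre = nx.from_numpy_array(pre_adj)
    g_post = nx.from_numpy_array(post_adj)
    union = nx.from_numpy_array(np.maximum(pre_adj, post_adj))
    pos = nx.spring_layout(union, seed=7)
    color = modules.color(module)
    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for ax, g, title in ((axes[0], g_pre, "pre-treatment"), (axes[1], g_post, "post-treatment")):
        nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.4, width=0.7)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_size=40, node_color=color, edgecolors="k", linewidths=0.3)
        ax.set_title(f"{title} ({g.number_of_edges()} edges)")
        ax.axis("off")
    fig.suptitle(f"module {module} ({color}), tau={tau}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
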