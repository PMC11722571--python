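"""Plot helpers: envelope curves, bipartite webs, marginal curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .networks import BipartiteMatrix
from .spatial import RingKEnvelope


def plot_envelope(env: RingKEnvelope, path=None, title=""):
    """Observed ring-K curve against its Monte Carlo envelope."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(env.radii, env.lower, env.upper, color="red", alpha=0.25,
                    label=f"{100 * (1 - env.alpha):g}% envelope ({env.n_sim} sims)")
    ax.plot(env.radii, env.observed, "k-o", ms=3, label="observed")
    out = env.exceed != 0
    if out.any():
        ax.plot(env.radii[out], env.observed[out], "r*", ms=10, label="outside")
    ax.set_xlabel("radius r (m)")
    ax.set_ylabel(f"K(r) - K(r - {env.ring_width:g})")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bipartite(m: BipartiteMatrix, path=None, title=""):
    """Two-column interaction web; edge width scales with weight."""
    fig, ax = plt.subplots(figsize=(7, max(4, 0.3 * (len(m.row_species) + len(m.col_species)))))
    g = nx.Graph()
    g.add_nodes_from(m.row_species, bipartite=0)
    g.add_nodes_from(m.col_species, bipartite=1)
    wmax = m.weights.to_numpy().max() if not m.is_empty() else 1.0
    for r in m.row_species:
        for c in m.col_species:
            w = m.weights.loc[r, c]
            if w > 0:
                g.add_edge(r, c, weight=w)
    pos = {}
    for i, r in enumerate(m.row_species):
        pos[r] = (0, -i)
    for i, c in enumerate(m.col_species):
        pos[c] = (1, -i * len(m.row_species) / max(len(m.col_species), 1))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=40, node_color="forestgreen")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    for u, v, d in g.edges(data=True):
        ax.plot(*zip(pos[u], pos[v]), color="gray",
                lw=0.5 + 3 * d["weight"] / wmax, alpha=0.6, zorder=0)
    ax.set_title(title or m.weight_kind)
    ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_marginal_curves(curves_by_type: dict, ylabel: str, path=None):
    """Expected-response curves (one per forest type) with intervals."""
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"mature": "darkgreen", "successional": "peru"}
    for ft, df in curves_by_type.items():
        c = colors.get(ft, None)
        ax.plot(df.dbh, df["mean"], label=ft, color=c)
        ax.fill_between(df.dbh, df.lower, df.upper, alpha=0.2, color=c)
    ax.set_xlabel("dbh (cm)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
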