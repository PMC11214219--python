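"""Deterministic force-directed layout and publication-style plots.

The layout is the Fruchterman-Reingold algorithm on absolute edge weights:
repulsion k^2/d between all node pairs, attraction |w_ij| d^2/k along
edges, a linearly cooling displacement cap, and final normalization to the
unit square.  Everything is seeded, so identical network + seed gives
identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "symptomnet"  # deterministic SVG ids
import matplotlib.pyplot as plt

from .ggm import PartialCorrelationNetwork

__all__ = [
    "LayoutCoordinates",
    "fruchterman_reingold",
    "render_network",
    "plot_centrality",
    "plot_edge_ci",
    "plot_case_drop",
]

EDGE_POSITIVE_COLOR = "blue"
EDGE_NEGATIVE_COLOR = "red"
_SVG_METADATA = {"Date": None}  # keep SVG output byte-stable across runs


@dataclass
class LayoutCoordinates:
    xy: np.ndarray  # (p, 2) in the unit square
    seed: int
    iterations: int
    final_displacement: float
    node_names: list[str]


def _weights(network) -> np.ndarray:
    if isinstance(network, PartialCorrelationNetwork):
        return network.weights
    return np.asarray(network, dtype=float)


def _node_names(network, p):
    if isinstance(network, PartialCorrelationNetwork):
        return list(network.node_names)
    return [f"V{i + 1}" for i in range(p)]


def fruchterman_reingold(
    network, seed: int = 0, iterations: int = 500
) -> LayoutCoordinates:
    """Seeded force-directed layout; coordinates normalized to [0, 1]^2."""
    w = _weights(network)
    p = w.shape[0]
    names = _node_names(network, p)
    if p == 1:
        return LayoutCoordinates(np.array([[0.5, 0.5]]), seed, 0, 0.0, names)
    a = np.abs(w)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(p, 2))
    k = np.sqrt(1.0 / p)
    t0 = 0.1
    disp_norm = 0.0
    for it in range(iterations):
        t = t0 * (1.0 - it / iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.maximum(np.linalg.norm(delta, axis=-1), 1e-9)
        # repulsive k^2/d between all pairs; attractive |w| d^2/k along edges
        force = k * k / dist**2 - a * dist / k
        np.fill_diagonal(force, 0.0)
        disp = (force[:, :, None] * delta / dist[:, :, None]).sum(axis=1)
        lengths = np.maximum(np.linalg.norm(disp, axis=1), 1e-12)
        pos = pos + disp / lengths[:, None] * np.minimum(lengths, t)[:, None]
        disp_norm = float(lengths.max())
    span = pos.max(axis=0) - pos.min(axis=0)
    span[span == 0] = 1.0
    pos = (pos - pos.min(axis=0)) / span
    return LayoutCoordinates(pos, seed, iterations, disp_norm, names)


def render_network(network, coords: LayoutCoordinates, path, edge_ci=None) -> None:
    """Draw the network: blue positive / red negative edges, stroke width
    proportional to |weight|, labeled nodes.  SVG output carries no
    timestamp.  If ``edge_ci`` (an EdgeBootstrapResult) is given, a CI
    whisker panel is added."""
    w = _weights(network)
    p = w.shape[0]
    names = _node_names(network, p)
    if coords.xy.shape[0] != p:
        raise ValueError("coordinates do not cover all nodes")
    ncols = 2 if edge_ci is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 6))
    ax = axes[0] if ncols == 2 else axes
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] != 0.0:
                color = EDGE_POSITIVE_COLOR if w[i, j] > 0 else EDGE_NEGATIVE_COLOR
                ax.plot(
                    coords.xy[[i, j], 0],
                    coords.xy[[i, j], 1],
                    color=color,
                    linewidth=max(8.0 * abs(w[i, j]), 0.2),
                    zorder=1,
                    solid_capstyle="round",
                )
    ax.scatter(coords.xy[:, 0], coords.xy[:, 1], s=900, c="#f2f2f2",
               edgecolors="black", zorder=2)
    for i, name in enumerate(names):
        ax.annotate(name, coords.xy[i], ha="center", va="center", fontsize=7, zorder=3)
    ax.set_xlim(-0.15, 1.15)
    ax.set_ylim(-0.15, 1.15)
    ax.set_axis_off()
    if edge_ci is not None:
        _edge_ci_panel(axes[1], edge_ci)
    fig.tight_layout()
    _save(fig, path)


def _edge_ci_panel(ax, boot) -> None:
    order = np.argsort(boot.estimate)
    y = np.arange(len(order))
    ax.hlines(y, boot.ci_lower[order], boot.ci_upper[order], color="lightgray")
    ax.plot(boot.boot_mean[order], y, "o", ms=3, color="black", label="bootstrap mean")
    ax.plot(boot.estimate[order], y, "o", ms=3, color="red", label="sample")
    labels = [
        f"{boot.node_names[i]}--{boot.node_names[j]}" for i, j in np.array(boot.edge_index)[order]
    ]
    ax.set_yticks(y, labels, fontsize=6)
    ax.axvline(0.0, color="black", lw=0.5)
    ax.set_xlabel("edge weight")
    ax.legend(fontsize=7)


def plot_edge_ci(boot, path) -> None:
    """Bootstrap CI whisker plot for the edge weights."""
    fig, ax = plt.subplots(figsize=(6, 6))
    _edge_ci_panel(ax, boot)
    fig.tight_layout()
    _save(fig, path)


def plot_centrality(centrality_table, path) -> None:
    """z-scored centrality profile plot (one panel per index)."""
    df = centrality_table.table
    indices = [c for c in df.columns if c.startswith("z_")]
    fig, axes = plt.subplots(1, len(indices), figsize=(3 * len(indices), 4), sharey=True)
    for ax, idx in zip(np.atleast_1d(axes), indices):
        ax.plot(df[idx].to_numpy(), range(len(df)), "o-")
        ax.set_title(idx[2:], fontsize=8)
        ax.axvline(0.0, color="gray", lw=0.5)
    np.atleast_1d(axes)[0].set_yticks(range(len(df)), df.index, fontsize=7)
    fig.tight_layout()
    _save(fig, path)


def plot_case_drop(curve, path) -> None:
    """Stability curves: median (with 5-95% band) of subsample-vs-full
    centrality correlations against the proportion of cases dropped."""
    fig, ax = plt.subplots(figsize=(6, 4))
    s = curve.summary()
    for idx, sub in s.groupby("index"):
        ax.plot(sub["drop_prop"], sub["median"], "o-", label=idx)
        ax.fill_between(sub["drop_prop"], sub["q05"], sub["q95"], alpha=0.15)
    ax.axhline(0.7, color="gray", lw=0.5, ls="--")
    ax.set_xlabel("proportion of cases dropped")
    ax.set_ylabel("correlation with full-sample centrality")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save(fig, path)


def _save(fig, path) -> None:
    path = str(path)
    if path.endswith(".svg"):
        fig.savefig(path, metadata=_SVG_METADATA)
    else:
        fig.savefig(path, dpi=150)
    plt.close(fig)
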