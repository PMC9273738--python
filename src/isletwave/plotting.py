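"""Figure helpers: network layouts over ROI positions, binarized rasters,
active-fraction curves. All functions write vector files and return the
matplotlib figure for further styling."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .activation import ActivationProfile, active_fraction_curve
from .network import FunctionalNetwork

__all__ = ["plot_network", "plot_raster", "plot_active_fraction"]


def plot_network(net: FunctionalNetwork, path: str | Path | None = None):
    """Draw the functional network at the ROI coordinates."""
    fig, ax = plt.subplots(figsize=(5, 4))
    pos = {n: d.get("pos", (0.0, 0.0)) for n, d in net.graph.nodes(data=True)}
    for u, v in net.graph.edges():
        (x1, y1), (x2, y2) = pos[u], pos[v]
        ax.plot([x1, x2], [y1, y2], color="0.6", lw=0.5, zorder=1)
    xs, ys = zip(*pos.values())
    degrees = [net.graph.degree(n) for n in pos]
    sc = ax.scatter(xs, ys, c=degrees, s=30, cmap="viridis", zorder=2)
    fig.colorbar(sc, ax=ax, label="node degree")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"r > {net.r_threshold:g}, E = {net.n_edges}")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_raster(raster: pd.DataFrame, path: str | Path | None = None):
    """Raster of binarized activity colored by wave id (long-format table)."""
    fig, ax = plt.subplots(figsize=(7, 3))
    if not raster.empty:
        ax.scatter(
            raster["time_s"], raster["cell_index"],
            c=raster["wave_id"], s=1, cmap="tab20", marker="|",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_active_fraction(
    profiles: dict[str, ActivationProfile],
    time_grid: np.ndarray,
    path: str | Path | None = None,
):
    """Fraction-of-active-cells curves, one line per labeled condition."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        ax.step(time_grid, active_fraction_curve(prof, time_grid), where="post", label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction of active cells")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig
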