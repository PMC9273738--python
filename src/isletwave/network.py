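"""Threshold-correlation functional beta-cell networks.

Cells are nodes; an undirected edge joins two cells whose activity traces in
the analysis window exceed a Pearson-correlation threshold (r > 0.8 by
default). The two headline diagnostics are the average node degree (overall
coherence of collective activity) and the average clustering coefficient
(local functional segregation: how strongly a cell's partners are
themselves interconnected).

By default correlations are computed on the band-passed (0.04-2 Hz) traces
so slow drift cannot inflate them; a raw-trace mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .core import IsletRecording
from .waves import bandpass_filter

__all__ = [
    "FunctionalNetwork",
    "correlation_matrix",
    "build_network",
    "average_node_degree",
    "average_clustering_coefficient",
    "write_graphml",
]


@dataclass
class FunctionalNetwork:
    """Thresholded-correlation graph over ROIs with positions attached."""

    graph: nx.Graph
    r_threshold: float
    analysis_window: tuple[float, float] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def clustering(self) -> dict[str, float]:
        return nx.clustering(self.graph)

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(u, v, d.get("r", np.nan)) for u, v, d in self.graph.edges(data=True)]


def correlation_matrix(
    recording: IsletRecording,
    window: tuple[float, float] | None = None,
    mode: str = "bandpassed",
    low: float = 0.04,
    high: float = 2.0,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson correlation of (windowed) traces.

    ``mode='bandpassed'`` (default) filters each trace to the fast
    oscillation band before correlating; ``mode='raw'`` correlates the raw
    traces. A constant trace cannot be correlated: its row and column are
    set to 0 (diagonal stays 1) with a warning.
    """
    if mode not in ("bandpassed", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    rec = recording if window is None else recording.window(*window)
    if window is not None and (window[1] - window[0]) < 60.0:
        raise ValueError("analysis window must span at least 60 s")
    traces = rec.traces
    if mode == "bandpassed":
        traces = [bandpass_filter(t, low=low, high=high) for t in traces]
    data = np.stack([t.samples for t in traces])
    sd = data.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        bad = [traces[i].roi_id for i in np.flatnonzero(constant)]
        warnings.warn(f"constant trace(s) in window, zeroing correlations: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr, rec.roi_ids


def build_network(
    corr: np.ndarray,
    roi_ids: Sequence[str],
    positions: dict[str, tuple[float, float]] | None = None,
    r_threshold: float = 0.8,
    analysis_window: tuple[float, float] | None = None,
) -> FunctionalNetwork:
    """Edge (i, j) iff corr[i, j] > r_threshold (strict), i != j.

    All ROIs become nodes, including unconnected ones, so metrics remain
    comparable across epochs at fixed N.
    """
    if not (-1.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie strictly inside (-1, 1)")
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1] or corr.shape[0] != len(roi_ids):
        raise ValueError("corr must be square and match roi_ids")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("corr must be symmetric")
    g = nx.Graph()
    for rid in roi_ids:
        attrs = {}
        if positions and rid in positions:
            attrs["pos"] = tuple(positions[rid])
        g.add_node(rid, **attrs)
    n = len(roi_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] > r_threshold:
                g.add_edge(roi_ids[i], roi_ids[j], r=float(corr[i, j]))
    return FunctionalNetwork(graph=g, r_threshold=r_threshold, analysis_window=analysis_window)


def write_graphml(net: FunctionalNetwork, path) -> None:
    """Write the network as GraphML (positions flattened to x/y attributes)."""
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        attrs = {}
        if "pos" in data:
            attrs["x"], attrs["y"] = (float(v) for v in data["pos"])
        g.add_node(node, **attrs)
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, r=float(data.get("r", 0.0)))
    g.graph["r_threshold"] = float(net.r_threshold)
    nx.write_graphml(g, path)


def average_node_degree(net: FunctionalNetwork) -> float:
    """Mean node degree, 2|E|/N."""
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    return 2.0 * net.n_edges / net.n_nodes


def average_clustering_coefficient(net: FunctionalNetwork) -> float:
    """Mean local clustering coefficient; nodes with degree < 2 count as 0."""
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    return float(nx.average_clustering(net.graph))
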