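"""End-to-end orchestration: per-epoch event, network and wave analysis.

A run takes one recording (read from disk or simulated), a list of pH
epochs, and stage parameter blocks, and produces per epoch: the event
catalog and activity table, the functional-network metrics and the
relative wave-size distribution, plus an activation profile for the
glucose-step phase. Analysis windows skip a configurable equilibration
interval after each solution switch. The whole run is deterministic under
a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import activation as act
from . import events as ev
from . import network as nw
from . import waves as wv
from .core import IsletRecording
from .io import write_recording, write_summary
from .synthetic import IsletGeometry, SimulationConfig, simulate_recording

logger = logging.getLogger("isletwave")

__all__ = ["EpochDef", "RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class EpochDef:
    """One contiguous interval at constant bath pH."""

    label: str
    ph: float
    start_s: float
    end_s: float


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (a SimulationConfig) or a pre-loaded recording is
    the input. ``post_switch_exclusion`` seconds after each epoch start are
    excluded from analysis (bath exchange is not instantaneous).
    """

    epochs: list[EpochDef]
    simulation: SimulationConfig | None = None
    stimulus_onset: float | None = None
    post_switch_exclusion: float = 60.0
    z_threshold: float = 4.0
    scales: tuple[float, ...] = ev.DEFAULT_SCALES
    baseline_window: float = 120.0
    r_threshold: float = 0.8
    bandpass: tuple[float, float] = (0.04, 2.0)
    theta_on: float = 2.0
    theta_off: float = 0.5
    time_tolerance: float = 1.0
    activation_k_sd: float = 3.0
    activation_sustain: float = 5.0
    out_dir: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        ordered = sorted(self.epochs, key=lambda e: e.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.end_s > b.start_s:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap")
        for e in self.epochs:
            if e.end_s <= e.start_s:
                raise ValueError(f"epoch {e.label!r} is empty")


def _epoch_window(epoch: EpochDef, exclusion: float) -> tuple[float, float]:
    return (epoch.start_s + exclusion, epoch.end_s)


def run_pipeline(
    config: RunConfig,
    recording: IsletRecording | None = None,
    geometry: IsletGeometry | None = None,
) -> dict[str, Any]:
    """Run every analysis stage per epoch and return a structured report.

    Stage failures are caught per epoch and stage: the report marks the
    stage ``failed`` with the error message while independent stages still
    run. When ``config.out_dir`` is set, tables and a flat key-value
    summary (with a sha256 digest for determinism checks) are written
    there.
    """
    config.validate()
    if recording is None:
        if config.simulation is None:
            raise ValueError("need either a recording or a simulation config")
        sim = replace(config.simulation, seed=config.seed)
        recording, truth = simulate_recording(sim)
        if geometry is None:
            geometry = _geometry_from_positions(recording)
    else:
        if geometry is None:
            geometry = _geometry_from_positions(recording)

    report: dict[str, Any] = {"epochs": {}, "seed": config.seed}
    summary: dict[str, Any] = {"seed": config.seed}

    # events are detected once on the full normalized traces and assigned
    # to epochs by peak time, so epoch boundaries cannot split an event
    normalized = [
        ev.normalize_trace(t, baseline_window=config.baseline_window)
        for t in recording.traces
    ]
    all_events: list[ev.CalciumEvent] = []
    for z in normalized:
        all_events.extend(
            ev.detect_events(z, z_threshold=config.z_threshold, scales=config.scales)
        )

    if config.stimulus_onset is not None:
        try:
            profile = act.build_activation_profile(
                recording,
                stimulus_onset=config.stimulus_onset,
                k_sd=config.activation_k_sd,
                sustain=config.activation_sustain,
                baseline_window=config.baseline_window,
            )
            report["activation"] = {
                "status": "ok",
                "profile": profile,
                "premature_fraction": act.premature_fraction(profile),
                "n_nonresponders": profile.n_nonresponders,
            }
            summary["activation.premature_fraction"] = act.premature_fraction(profile)
            summary["activation.median_delay_s"] = float(
                profile.table["delay_from_stimulus"].median()
            )
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.exception("activation stage failed")
            report["activation"] = {"status": "failed", "error": str(exc)}

    for epoch in config.epochs:
        epoch_report: dict[str, Any] = {}
        w0, w1 = _epoch_window(epoch, config.post_switch_exclusion)
        duration = w1 - w0

        try:
            epoch_events = [e for e in all_events if w0 <= e.peak_time < w1]
            activity = ev.compute_activity(
                epoch_events, duration=duration, roi_ids=recording.roi_ids
            )
            epoch_report["events"] = {
                "status": "ok",
                "catalog": epoch_events,
                "activity": activity,
            }
            summary[f"{epoch.label}.events_per_minute"] = float(
                activity["events_per_minute"].mean()
            )
            summary[f"{epoch.label}.auc_per_minute"] = float(
                activity["auc_per_minute"].mean()
            )
            summary[f"{epoch.label}.n_active_rois"] = int(activity["is_active"].sum())
        except Exception as exc:  # noqa: BLE001
            logger.exception("event stage failed for epoch %s", epoch.label)
            epoch_report["events"] = {"status": "failed", "error": str(exc)}

        try:
            corr, ids = nw.correlation_matrix(
                recording,
                window=(w0, w1),
                low=config.bandpass[0],
                high=config.bandpass[1],
            )
            net = nw.build_network(
                corr,
                ids,
                positions=recording.positions,
                r_threshold=config.r_threshold,
                analysis_window=(w0, w1),
            )
            epoch_report["network"] = {
                "status": "ok",
                "network": net,
                "average_node_degree": nw.average_node_degree(net),
                "average_clustering_coefficient": nw.average_clustering_coefficient(net),
            }
            summary[f"{epoch.label}.avg_node_degree"] = nw.average_node_degree(net)
            summary[f"{epoch.label}.avg_clustering"] = nw.average_clustering_coefficient(net)
        except Exception as exc:  # noqa: BLE001
            logger.exception("network stage failed for epoch %s", epoch.label)
            epoch_report["network"] = {"status": "failed", "error": str(exc)}

        try:
            windowed = recording.window(w0, w1)
            filtered = [
                wv.bandpass_filter(t, low=config.bandpass[0], high=config.bandpass[1])
                for t in windowed.traces
            ]
            binary = wv.binarize_recording(
                filtered, theta_on=config.theta_on, theta_off=config.theta_off
            )
            seg = wv.segment_waves(binary, geometry, time_tolerance=config.time_tolerance)
            epoch_report["waves"] = {"status": "ok", "segmentation": seg}
            if seg.n_waves:
                sizes = seg.relative_sizes()
                summary[f"{epoch.label}.n_waves"] = seg.n_waves
                summary[f"{epoch.label}.median_wave_size"] = float(np.median(sizes))
        except Exception as exc:  # noqa: BLE001
            logger.exception("wave stage failed for epoch %s", epoch.label)
            epoch_report["waves"] = {"status": "failed", "error": str(exc)}

        report["epochs"][epoch.label] = epoch_report

    report["summary"] = summary
    digest_src = "\n".join(f"{k}={summary[k]!r}" for k in sorted(summary))
    report["summary_digest"] = hashlib.sha256(digest_src.encode()).hexdigest()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_recording(recording, out / "traces.csv", out / "coords.csv")
        _write_tables(report, out)
        write_summary({**summary, "digest": report["summary_digest"]}, out / "summary.txt")
    return report


def _geometry_from_positions(recording: IsletRecording) -> IsletGeometry:
    """Spatial neighbor graph from ROI coordinates alone: all pairs closer
    than 2x the median nearest-neighbor distance are neighbors."""
    from scipy.spatial import distance

    pts = np.array([recording.positions[r] for r in recording.roi_ids])
    n = pts.shape[0]
    if n == 2:
        return IsletGeometry(pts, frozenset({(0, 1)}))
    dmat = distance.squareform(distance.pdist(pts))
    np.fill_diagonal(dmat, np.inf)
    cutoff = 2.0 * float(np.median(dmat.min(axis=1)))
    edges = {
        (i, j) for i in range(n) for j in range(i + 1, n) if dmat[i, j] <= cutoff
    }
    return IsletGeometry(pts, frozenset(edges))


def _write_tables(report: dict[str, Any], out: Path) -> None:
    for label, epoch_report in report["epochs"].items():
        if epoch_report.get("events", {}).get("status") == "ok":
            cat = epoch_report["events"]["catalog"]
            pd.DataFrame([e.__dict__ for e in cat]).to_csv(
                out / f"{label}_events.csv", index=False
            )
            epoch_report["events"]["activity"].to_csv(out / f"{label}_activity.csv")
        if epoch_report.get("network", {}).get("status") == "ok":
            net = epoch_report["network"]["network"]
            pd.DataFrame(net.edge_list(), columns=["roi_a", "roi_b", "r"]).to_csv(
                out / f"{label}_edges.csv", index=False
            )
            nw.write_graphml(net, out / f"{label}_network.graphml")
        if epoch_report.get("waves", {}).get("status") == "ok":
            seg = epoch_report["waves"]["segmentation"]
            pd.DataFrame(
                [
                    {
                        "wave_id": w.wave_id,
                        "n_cells": w.n_cells,
                        "relative_size": w.relative_size,
                        "start_time": w.start_time,
                        "duration": w.duration,
                    }
                    for w in seg.waves
                ]
            ).to_csv(out / f"{label}_waves.csv", index=False)
    if report.get("activation", {}).get("status") == "ok":
        report["activation"]["profile"].table.to_csv(out / "activation_profile.csv")
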