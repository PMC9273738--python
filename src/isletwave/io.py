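"""Reading and writing the pipeline's text formats.

Traces: delimited table, first column ``time_s``, one column per ROI,
header row of ROI ids. Coordinates: delimited table ``roi_id, x, y``.
Ground truth: JSON sidecar with per-cell activation times, spike times and
wave ids. Simulation configs: YAML mirroring SimulationConfig field names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import IsletRecording, ProtocolEvent, RoiTrace
from .synthetic import GroundTruth, SimulationConfig

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "load_simulation_config",
    "dump_simulation_config",
    "write_summary",
]


def write_recording(
    recording: IsletRecording, trace_path: str | Path, coord_path: str | Path
) -> None:
    """Write traces and ROI coordinates as delimited text tables."""
    df = recording.as_frame().reset_index()
    df.to_csv(trace_path, index=False)
    coords = pd.DataFrame(
        [(rid, x, y) for rid, (x, y) in recording.positions.items()],
        columns=["roi_id", "x", "y"],
    )
    coords.to_csv(coord_path, index=False, float_format="%.6g")


def read_recording(
    trace_path: str | Path, coord_path: str | Path, protocol: list[ProtocolEvent] | None = None
) -> IsletRecording:
    """Read a trace table and coordinate table into a validated recording.

    The sampling rate is inferred from the time column and required to be
    uniform within 1%; the two files must agree on the ROI set.
    """
    traces = pd.read_csv(trace_path)
    if traces.shape[1] < 2 or traces.columns[0] != "time_s":
        raise ValueError(f"{trace_path}: first column must be 'time_s'")
    if traces.isna().any().any():
        raise ValueError(f"{trace_path}: ragged or missing values")
    t = traces["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{trace_path}: time column is not strictly increasing")
    mean_dt = float(np.mean(dt))
    if np.max(np.abs(dt - mean_dt)) > 0.01 * mean_dt:
        raise ValueError(f"{trace_path}: sampling is not uniform within 1%")
    fs = 1.0 / mean_dt

    coords = pd.read_csv(coord_path)
    required = {"roi_id", "x", "y"}
    if not required.issubset(coords.columns):
        raise ValueError(f"{coord_path}: needs columns {sorted(required)}")
    coords["roi_id"] = coords["roi_id"].astype(str)
    trace_ids = [str(c) for c in traces.columns[1:]]
    coord_ids = set(coords["roi_id"])
    missing = sorted(set(trace_ids) - coord_ids)
    extra = sorted(coord_ids - set(trace_ids))
    if missing or extra:
        raise ValueError(
            f"ROI mismatch between {trace_path} and {coord_path}: "
            f"missing coordinates for {missing}, extra coordinates for {extra}"
        )
    positions = {
        row.roi_id: (float(row.x), float(row.y)) for row in coords.itertuples()
    }
    return IsletRecording(
        traces=[
            RoiTrace(rid, traces[rid].to_numpy(dtype=float), fs) for rid in trace_ids
        ],
        positions=positions,
        protocol=protocol or [],
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "activation_time": truth.activation_time.tolist(),
        "spike_times": [s.tolist() for s in truth.spike_times],
        "wave_membership": [
            {"cell": c, "spike": s, "wave": w} for (c, s), w in sorted(truth.wave_membership.items())
        ],
        "initiating_cell": {str(k): v for k, v in truth.initiating_cell.items()},
        "initiation_time": {str(k): v for k, v in truth.initiation_time.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        activation_time=np.asarray(payload["activation_time"], dtype=float),
        spike_times=[np.asarray(s, dtype=float) for s in payload["spike_times"]],
        wave_membership={
            (d["cell"], d["spike"]): d["wave"] for d in payload["wave_membership"]
        },
        initiating_cell={int(k): v for k, v in payload["initiating_cell"].items()},
        initiation_time={int(k): v for k, v in payload["initiation_time"].items()},
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML; keys mirror the field names."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "ph_protocol" in raw:
        raw["ph_protocol"] = tuple(
            (float(s), float(p)) for s, p in raw["ph_protocol"]
        )
    return SimulationConfig(**raw)


def dump_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    data = {
        k: getattr(config, k) for k in SimulationConfig.__dataclass_fields__
    }
    data["ph_protocol"] = [[float(s), float(p)] for s, p in config.ph_protocol]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_summary(summary: dict[str, Any], path: str | Path) -> None:
    """Flat ``key = value`` text summary, sorted for diffability."""
    lines = []
    for key in sorted(summary):
        v = summary[key]
        if isinstance(v, float):
            lines.append(f"{key} = {v:.6g}")
        else:
            lines.append(f"{key} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
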