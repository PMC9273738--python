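"""Core containers shared by all analysis stages.

An islet recording is a set of equally sampled fluorescence traces, one per
region of interest (ROI, one beta cell), together with the ROI centroid
positions and the stimulation protocol (glucose steps, bath-pH segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A parameter combination that cannot produce a valid simulation/run."""


class ZeroDispersionWarning(UserWarning):
    """A trace had no dispersion; normalization returned zeros."""


@dataclass(frozen=True)
class ProtocolEvent:
    """A change of bath condition at ``start_s`` (seconds from record start)."""

    start_s: float
    glucose_mM: float
    ph: float


@dataclass
class RoiTrace:
    """One ROI fluorescence time series at uniform sampling.

    Parameters
    ----------
    roi_id
        Identifier of the region of interest (one cell).
    samples
        Fluorescence values, arbitrary units (or z-units after normalization).
    sampling_rate
        Samples per second (Hz).
    """

    roi_id: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError(f"trace {self.roi_id!r} needs >= 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.roi_id!r} contains non-finite samples")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def window(self, start_s: float, end_s: float) -> "RoiTrace":
        """Slice the trace to [start_s, end_s); times restart at 0."""
        i0 = max(0, int(np.ceil(start_s * self.sampling_rate)))
        i1 = min(self.n_samples, int(np.ceil(end_s * self.sampling_rate)))
        if i1 - i0 < 2:
            raise ValueError("window contains fewer than 2 samples")
        return RoiTrace(self.roi_id, self.samples[i0:i1], self.sampling_rate)


@dataclass
class IsletRecording:
    """All ROI traces of one islet plus positions and protocol annotations."""

    traces: list[RoiTrace]
    positions: dict[str, tuple[float, float]]
    protocol: list[ProtocolEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("recording must contain at least one trace")
        ids = [t.roi_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate roi_id in traces")
        if set(ids) != set(self.positions):
            missing = set(ids) ^ set(self.positions)
            raise ValueError(f"traces and positions disagree on ROIs: {sorted(missing)}")
        n = {t.n_samples for t in self.traces}
        if len(n) != 1:
            raise ValueError("all traces must have equal length")
        fs = {t.sampling_rate for t in self.traces}
        if len(fs) != 1:
            raise ValueError("all traces must share one sampling rate")

    @property
    def roi_ids(self) -> list[str]:
        return [t.roi_id for t in self.traces]

    @property
    def sampling_rate(self) -> float:
        return self.traces[0].sampling_rate

    @property
    def n_samples(self) -> int:
        return self.traces[0].n_samples

    @property
    def duration(self) -> float:
        return self.traces[0].duration

    @property
    def times(self) -> np.ndarray:
        return self.traces[0].times

    def trace(self, roi_id: str) -> RoiTrace:
        for t in self.traces:
            if t.roi_id == roi_id:
                return t
        raise KeyError(roi_id)

    def matrix(self) -> np.ndarray:
        """(n_samples, n_rois) array in trace order."""
        return np.column_stack([t.samples for t in self.traces])

    def as_frame(self) -> pd.DataFrame:
        """Traces as a DataFrame indexed by time (s), one column per ROI."""
        return pd.DataFrame(
            self.matrix(), index=pd.Index(self.times, name="time_s"), columns=self.roi_ids
        )

    def window(self, start_s: float, end_s: float) -> "IsletRecording":
        return IsletRecording(
            traces=[t.window(start_s, end_s) for t in self.traces],
            positions=dict(self.positions),
            protocol=list(self.protocol),
        )

    def map_traces(self, fn) -> "IsletRecording":
        """Apply ``fn(RoiTrace) -> RoiTrace`` to every trace."""
        return IsletRecording(
            traces=[fn(t) for t in self.traces],
            positions=dict(self.positions),
            protocol=list(self.protocol),
        )


def robust_sd(x: Iterable[float]) -> float:
    """1.4826 x median absolute deviation — consistent for a normal sd."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))
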