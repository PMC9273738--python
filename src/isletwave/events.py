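"""Detection and quantification of significant [Ca2+]c events.

Each ROI trace is robustly z-normalized (rolling-median detrend, MAD scale),
then scanned for excursions above a z threshold at a ladder of box-smoothing
time scales, so that both brief spikes and slow, broad transients reach
significance at whichever scale matches their width. Overlapping candidates
from different scales collapse to the most significant one, and every
surviving event is measured on the unsmoothed normalized trace: peak height,
width at half of the peak amplitude, start time, and area under the curve.

Activity per ROI is summarized as events per minute and summed event AUC per
minute; a ROI counts as active when it carries more than 10 events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import RoiTrace, ZeroDispersionWarning, robust_sd

__all__ = [
    "CalciumEvent",
    "LogSummary",
    "HexbinSummary",
    "DEFAULT_SCALES",
    "normalize_trace",
    "detect_events",
    "compute_activity",
    "log_transform_summary",
    "hexbin_summary",
]

#: Box-smoothing scale ladder (s): bounded below by the sampling interval,
#: above by the slow-drift regime that the 0.04 Hz wave band edge excludes.
DEFAULT_SCALES: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


@dataclass(frozen=True)
class CalciumEvent:
    """One detected [Ca2+]c transient in one ROI.

    ``peak_height`` is in z-units of the normalized trace, ``halfwidth`` is
    the FWHM in seconds, ``auc`` the trapezoidal area (z-units * s) over the
    event support, and ``scale`` the smoothing scale that maximized
    significance.
    """

    roi_id: str
    start_time: float
    peak_time: float
    peak_height: float
    halfwidth: float
    auc: float
    scale: float


def normalize_trace(trace: RoiTrace, baseline_window: float = 120.0) -> RoiTrace:
    """Robust z-normalization: rolling-median detrend + MAD scaling.

    The rolling median (centered, ``baseline_window`` seconds) tracks the
    slowly varying baseline. The noise scale is the robust sd of the first
    differences divided by ``sqrt(2)``: transients are smooth on the sample
    scale while white noise is not, so the estimate stays anchored to the
    noise floor even in densely oscillating traces, where a plain MAD of
    the detrended samples would absorb signal. A constant trace yields all
    zeros and a :class:`ZeroDispersionWarning`.
    """
    fs = trace.sampling_rate
    if baseline_window < 10.0 / fs:
        raise ValueError("baseline_window must span at least 10 samples")
    w = max(3, int(round(baseline_window * fs)) | 1)  # odd window
    x = pd.Series(trace.samples)
    baseline = x.rolling(w, center=True, min_periods=1).median().to_numpy()
    detrended = trace.samples - baseline
    scale = robust_sd(np.diff(detrended)) / math.sqrt(2.0)
    if scale == 0.0:
        scale = robust_sd(detrended)
    if scale == 0.0:
        scale = float(np.std(detrended))
    if scale == 0.0:
        warnings.warn(
            f"trace {trace.roi_id!r} has zero dispersion; returning zeros",
            ZeroDispersionWarning,
        )
        return RoiTrace(trace.roi_id, np.zeros_like(detrended), fs)
    return RoiTrace(trace.roi_id, detrended / scale, fs)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, end) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.insert(starts, 0, 0)
    if mask[-1]:
        ends = np.append(ends, mask.size)
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class _Candidate:
    lo: int      # half-height interval start (smoothed trace)
    hi: int      # half-height interval end, exclusive
    peak: int    # argmax of the renormalized smoothed trace
    zmax: float
    scale: float


def _half_height_interval(z: np.ndarray, peak: int, half: float) -> tuple[int, int]:
    lo = peak
    while lo > 0 and z[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < z.size - 1 and z[hi + 1] >= half:
        hi += 1
    return lo, hi + 1


def detect_events(
    trace: RoiTrace,
    z_threshold: float = 4.0,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> list[CalciumEvent]:
    """Multi-scale detection of supra-threshold transients on a z-scored trace.

    Each scale uses a difference-of-boxes band filter — a box average over
    ``w`` samples minus a box average over ``4w`` samples — renormalized by
    the exact white-noise sd of that filter, ``sqrt(3 / (4w))``. The wide
    box subtracts the local pedestal, so a dense periodic train stays
    resolved into its individual oscillations instead of fusing into one
    broad excursion at the coarse scales, while an isolated broad transient
    still gains the full matched-filter boost. Contiguous excursions above
    ``z_threshold`` become candidates. Candidates from different scales whose
    half-height intervals overlap are resolved greedily in favour of the
    highest smoothed z. Event metrics are then measured on the *unsmoothed*
    normalized trace; events whose raw peak does not itself exceed the
    threshold are dropped.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if not len(scales):
        raise ValueError("scales must be non-empty")
    z = trace.samples
    fs = trace.sampling_rate
    n = z.size

    candidates: list[_Candidate] = []
    for s in scales:
        w = max(1, int(round(s * fs)))
        if w >= n:
            continue
        smoothed = uniform_filter1d(z, size=w, mode="nearest")
        pedestal = uniform_filter1d(z, size=min(4 * w, n), mode="nearest")
        zs = (smoothed - pedestal) / math.sqrt(3.0 / (4.0 * w))
        for lo, hi in _runs_above(zs > z_threshold):
            peak = lo + int(np.argmax(zs[lo:hi]))
            clo, chi = _half_height_interval(zs, peak, zs[peak] / 2.0)
            candidates.append(_Candidate(clo, chi, peak, float(zs[peak]), float(s)))

    # greedy cross-scale merge: keep the most significant candidate among
    # half-height-overlapping ones (deterministic: z desc, then index)
    candidates.sort(key=lambda c: (-c.zmax, c.lo, c.scale))
    accepted: list[_Candidate] = []
    for c in candidates:
        if all(c.hi <= a.lo or c.lo >= a.hi for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda c: c.lo)

    events: list[CalciumEvent] = []
    for k, c in enumerate(accepted):
        peak_idx = c.lo + int(np.argmax(z[c.lo:c.hi]))
        peak = float(z[peak_idx])
        if peak <= z_threshold:
            continue
        # half level from a 3-point median at the peak: the raw max
        # overestimates the amplitude by the noise extreme, which would
        # bias the halfwidth narrow
        lo3, hi3 = max(0, peak_idx - 1), min(n, peak_idx + 2)
        half = float(np.median(z[lo3:hi3])) / 2.0
        # support caps at midpoints to adjacent accepted candidates
        cap_lo = 0 if k == 0 else (accepted[k - 1].peak + c.peak) // 2
        cap_hi = n if k == len(accepted) - 1 else (c.peak + accepted[k + 1].peak) // 2 + 1

        # last sub-half-height sample before the peak
        i = peak_idx
        while i > cap_lo and z[i - 1] >= half:
            i -= 1
        start_idx = max(cap_lo, i - 1)
        j = peak_idx
        while j < cap_hi - 1 and z[j + 1] >= half:
            j += 1

        # AUC support: extend from half-height bounds to baseline crossings
        a = i
        while a > cap_lo and z[a - 1] > 0.0:
            a -= 1
        b = j
        while b < cap_hi - 1 and z[b + 1] > 0.0:
            b += 1

        # halfwidth: occupancy above half height within the support; under
        # symmetric noise the early/late crossings cancel, so this is
        # unbiased where a walk to the first sub-half sample is biased
        # narrow on shallow flanks
        n_above = int(np.count_nonzero(z[a : b + 1] >= half))
        halfwidth = max(n_above, 1) / fs

        support = np.clip(z[a : b + 1], 0.0, None)
        auc = float(np.trapezoid(support, dx=1.0 / fs)) if support.size > 1 else float(support.sum() / fs)

        events.append(
            CalciumEvent(
                roi_id=trace.roi_id,
                start_time=start_idx / fs,
                peak_time=peak_idx / fs,
                peak_height=peak,
                halfwidth=float(halfwidth),
                auc=max(auc, np.finfo(float).tiny),
                scale=c.scale,
            )
        )
    events.sort(key=lambda e: e.start_time)
    return events


def compute_activity(
    events: Iterable[CalciumEvent],
    duration: float,
    roi_ids: Sequence[str] | None = None,
    active_min_events: int = 10,
) -> pd.DataFrame:
    """Per-ROI activity table: event rate and summed AUC per minute.

    A ROI is ``is_active`` when it carries strictly more than
    ``active_min_events`` events. ROIs listed in ``roi_ids`` but without
    events appear as zero rows.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    minutes = duration / 60.0
    by_roi: dict[str, list[CalciumEvent]] = {}
    for ev in events:
        by_roi.setdefault(ev.roi_id, []).append(ev)
    ids = list(roi_ids) if roi_ids is not None else sorted(by_roi)
    for rid in by_roi:
        if rid not in ids:
            ids.append(rid)
    rows = []
    for rid in ids:
        evs = by_roi.get(rid, [])
        count = len(evs)
        rows.append(
            {
                "roi_id": rid,
                "event_count": count,
                "events_per_minute": count / minutes,
                "auc_per_minute": sum(e.auc for e in evs) / minutes,
                "is_active": count > active_min_events,
            }
        )
    return pd.DataFrame(rows).set_index("roi_id")


@dataclass(frozen=True)
class LogSummary:
    """Summary of a non-negative variable on the natural-log scale."""

    n: int
    n_excluded_zero: int
    log_mean: float
    log_sd: float
    geometric_mean: float


def log_transform_summary(values: Iterable[float]) -> LogSummary:
    """Natural-log summary of positive values; zeros excluded with a count."""
    v = np.asarray(list(values), dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    n_zero = int(np.sum(v == 0))
    pos = v[v > 0]
    if pos.size == 0:
        return LogSummary(0, n_zero, math.nan, math.nan, math.nan)
    logs = np.log(pos)
    return LogSummary(
        n=int(pos.size),
        n_excluded_zero=n_zero,
        log_mean=float(np.mean(logs)),
        log_sd=float(np.std(logs, ddof=1)) if pos.size > 1 else 0.0,
        geometric_mean=float(np.exp(np.mean(logs))),
    )


@dataclass
class HexbinSummary:
    """2-D histogram of event peak time vs log halfwidth."""

    counts: np.ndarray           # (time_bins, halfwidth_bins)
    time_edges: np.ndarray       # s
    log_halfwidth_edges: np.ndarray  # ln(s)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def hexbin_summary(
    events: Sequence[CalciumEvent],
    time_bins: int = 40,
    halfwidth_bins: int = 30,
) -> HexbinSummary:
    """Bin all events over a peak-time x log-halfwidth grid.

    Bin totals always sum to the number of events (edge-inclusive binning).
    """
    if not events:
        raise ValueError("need at least one event")
    t = np.array([e.peak_time for e in events])
    lw = np.log(np.array([e.halfwidth for e in events]))
    t_edges = np.linspace(t.min(), t.max() + np.finfo(float).eps, time_bins + 1)
    w_edges = np.linspace(lw.min(), lw.max() + np.finfo(float).eps, halfwidth_bins + 1)
    if t_edges[0] == t_edges[-1]:
        t_edges = np.array([t_edges[0] - 0.5, t_edges[0] + 0.5])
    if w_edges[0] == w_edges[-1]:
        w_edges = np.array([w_edges[0] - 0.5, w_edges[0] + 0.5])
    counts, t_edges, w_edges = np.histogram2d(t, lw, bins=[t_edges, w_edges])
    return HexbinSummary(counts=counts, time_edges=t_edges, log_halfwidth_edges=w_edges)
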