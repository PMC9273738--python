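"""Benchmark scenarios: end-to-end runs of the analysis on synthetic islets.

These helpers wire the simulator and every analysis stage together for the
package's standard validation scenarios — planted-event detection quality,
matched pH 7.1 vs 7.4 plateau comparisons, parameter recovery, the
constant-pH control — so tests and reproduction scripts share one code
path. All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import activation as act
from . import events as ev
from . import network as nw
from . import waves as wv
from .core import IsletRecording
from .pipeline import _geometry_from_positions
from .synthetic import PlantedEvent, SimulationConfig, plant_events, simulate_recording

__all__ = [
    "PlateauMetrics",
    "plateau_config",
    "analyze_plateau",
    "match_planted_events",
    "planted_event_benchmark",
    "ph_pair_comparison",
    "premature_fraction_recovery",
    "activation_delay_recovery",
    "control_thirds_ratio",
    "wave_recovery_full_coupling",
    "wave_recovery_zero_coupling",
]

#: analysis window starts this long after a solution switch (bath exchange
#: and filter transients settle)
EQUILIBRATION_S = 60.0


def plateau_config(
    ph: float, seed: int, minutes: float = 20.0, n_cells: int = 80, **overrides
) -> SimulationConfig:
    """A plateau-phase scenario: all cells active from t=0 at constant pH."""
    kw = dict(
        n_cells=n_cells,
        duration=minutes * 60.0,
        stim_onset=0.0,
        base_delay_mean=0.0,
        base_delay_sd=0.0,
        ph_protocol=((0.0, ph),),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass(frozen=True)
class PlateauMetrics:
    """Per-recording summary of all plateau-phase analyses."""

    events_per_minute: float
    average_node_degree: float
    average_clustering: float
    median_wave_size: float
    n_waves: int
    n_cells: int


def analyze_plateau(config: SimulationConfig) -> PlateauMetrics:
    """Simulate one plateau recording and run the full analysis chain."""
    recording, _ = simulate_recording(config)
    geometry = _geometry_from_positions(recording)
    window = (EQUILIBRATION_S, recording.duration)
    minutes = (window[1] - window[0]) / 60.0

    n_events = 0
    for tr in recording.traces:
        z = ev.normalize_trace(tr)
        n_events += sum(
            1 for e in ev.detect_events(z) if window[0] <= e.peak_time < window[1]
        )
    rate = n_events / len(recording.traces) / minutes

    corr, ids = nw.correlation_matrix(recording, window=window)
    net = nw.build_network(corr, ids, positions=recording.positions)

    windowed = recording.window(*window)
    filtered = [wv.bandpass_filter(t) for t in windowed.traces]
    binary = wv.binarize_recording(filtered)
    seg = wv.segment_waves(binary, geometry)
    sizes = seg.relative_sizes()

    return PlateauMetrics(
        events_per_minute=rate,
        average_node_degree=nw.average_node_degree(net),
        average_clustering=nw.average_clustering_coefficient(net),
        median_wave_size=float(np.median(sizes)) if sizes.size else float("nan"),
        n_waves=seg.n_waves,
        n_cells=config.n_cells,
    )


def match_planted_events(detected, truth: list[PlantedEvent]):
    """Greedy 1-1 matching of detected events to planted truth by peak time."""
    matches = []
    used: set[int] = set()
    for p in truth:
        best = None
        for k, e in enumerate(detected):
            if k in used or abs(e.peak_time - p.center_time) >= p.fwhm:
                continue
            if best is None or abs(e.peak_time - p.center_time) < abs(
                detected[best].peak_time - p.center_time
            ):
                best = k
        if best is not None:
            used.add(best)
            matches.append((p, detected[best]))
    return matches


def planted_event_benchmark(seed: int, n_events: int = 100) -> dict[str, float]:
    """Detection quality on planted Gaussians (peak 6-10 sd, FWHM 2-20 s, 2 Hz)."""
    rng = np.random.default_rng(seed)
    amps = rng.uniform(6.0, 10.0, n_events)
    fwhms = rng.uniform(2.0, 20.0, n_events)
    trace, truth = plant_events(
        n_events, amps, fwhms, baseline_sd=0.5, seed=seed + 1,
        sampling_rate=2.0, spacing=80.0,
    )
    detected = ev.detect_events(ev.normalize_trace(trace))
    matches = match_planted_events(detected, truth)
    rel_err = [abs(e.halfwidth - p.fwhm) / p.fwhm for p, e in matches]
    return {
        "recall": len(matches) / len(truth),
        "precision": len(matches) / len(detected) if detected else 0.0,
        "halfwidth_mean_rel_err": float(np.mean(rel_err)) if rel_err else float("nan"),
        "n_events": n_events,
    }


def ph_pair_comparison(
    n_pairs: int, seed: int, minutes: float = 20.0, n_cells: int = 80
) -> list[tuple[PlateauMetrics, PlateauMetrics]]:
    """Matched pH 7.4 / pH 7.1 plateau recordings, one pair per seed."""
    pairs = []
    for k in range(n_pairs):
        m74 = analyze_plateau(plateau_config(7.4, seed + 2 * k, minutes, n_cells))
        m71 = analyze_plateau(plateau_config(7.1, seed + 2 * k + 1, minutes, n_cells))
        pairs.append((m74, m71))
    return pairs


def premature_fraction_recovery(
    n_seeds: int, seed: int, configured: float = 0.10, n_cells: int = 80
) -> list[float]:
    """Recovered pre-stimulus-active fraction, one value per seed."""
    fracs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_cells=n_cells,
            prestim_active_fraction=configured,
            ph_protocol=((0.0, 7.1),),
            seed=seed + k,
        )
        recording, _ = simulate_recording(cfg)
        profile = act.build_activation_profile(recording, stimulus_onset=cfg.stim_onset)
        fracs.append(act.premature_fraction(profile))
    return fracs


def activation_delay_recovery(
    n_seeds: int, seed: int, ph: float = 7.4, n_cells: int = 80
) -> tuple[float, float, int]:
    """(pooled mean delay, pooled median delay, n cells pooled) after the step."""
    delays: list[float] = []
    for k in range(n_seeds):
        cfg = SimulationConfig(n_cells=n_cells, ph_protocol=((0.0, ph),), seed=seed + k)
        recording, _ = simulate_recording(cfg)
        profile = act.build_activation_profile(recording, stimulus_onset=cfg.stim_onset)
        delays.extend(profile.table["delay_from_stimulus"].tolist())
    return float(np.mean(delays)), float(np.median(delays)), len(delays)


def control_thirds_ratio(
    n_seeds: int, seed: int, minutes: float = 90.0, n_cells: int = 80
) -> list[float]:
    """Last-third / first-third event-rate ratio under constant pH 7.4."""
    ratios = []
    for k in range(n_seeds):
        cfg = plateau_config(7.4, seed + k, minutes=minutes, n_cells=n_cells)
        recording, _ = simulate_recording(cfg)
        # thirds of the analysis window (equilibration excluded, as always)
        third = (recording.duration - EQUILIBRATION_S) / 3.0
        counts = [0, 0, 0]
        for tr in recording.traces:
            for e in ev.detect_events(ev.normalize_trace(tr)):
                if e.peak_time < EQUILIBRATION_S:
                    continue
                counts[min(2, int((e.peak_time - EQUILIBRATION_S) // third))] += 1
        ratios.append(counts[2] / counts[0] if counts[0] else float("nan"))
    return ratios


def _wave_sizes_from_recording(recording: IsletRecording) -> np.ndarray:
    geometry = _geometry_from_positions(recording)
    windowed = recording.window(EQUILIBRATION_S, recording.duration)
    filtered = [wv.bandpass_filter(t) for t in windowed.traces]
    binary = wv.binarize_recording(filtered)
    seg = wv.segment_waves(binary, geometry)
    # a wave straddling either window edge is truncated; keep only waves
    # fully inside the analysis window
    return np.array(
        [
            w.relative_size
            for w in seg.waves
            if w.start_time > 1.0 and w.end_time < windowed.duration - 1.0
        ]
    )


def wave_recovery_full_coupling(seed: int) -> np.ndarray:
    """Relative sizes of detected waves when every cascade recruits all cells.

    Low initiation rate and a long refractory keep cascades isolated, so
    every detected wave should span the whole islet (relative size 1).
    """
    cfg = plateau_config(
        7.4, seed, minutes=20.0, n_cells=12,
        coupling_prob=1.0, plateau_freq=0.05, refractory=8.0, kernel_decay=1.5,
    )
    recording, _ = simulate_recording(cfg)
    return _wave_sizes_from_recording(recording)


def wave_recovery_zero_coupling(seed: int) -> np.ndarray:
    """Relative sizes of detected waves without propagation.

    With coupling off every cascade is one cell, so all detected waves
    should have relative size 1/N; the rate is kept low enough that two
    neighboring cells virtually never fire within the merge tolerance.
    """
    cfg = plateau_config(
        7.4, seed, minutes=20.0, n_cells=12,
        coupling_prob=0.0, plateau_freq=0.03, refractory=8.0, kernel_decay=1.0,
    )
    recording, _ = simulate_recording(cfg)
    return _wave_sizes_from_recording(recording)
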