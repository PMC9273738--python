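"""Synthetic islet recordings with ground truth.

The generator emulates the phenomenology of glucose-stimulated beta-cell
collectives observed with confocal Ca2+ imaging:

* a substimulatory baseline followed by a square glucose step,
* staircase-like recruitment of cells with a configurable delay
  distribution (acidic bath shifts delays earlier; a configurable fraction
  of cells is active already before the step, in contiguous clusters),
* a plateau phase of repetitive fast oscillations initiated cell-by-cell
  as a Poisson process and propagated to spatial neighbors as a stochastic
  cascade (gap-junction-like coupling), so that one initiation produces one
  intercellular wave,
* indicator kinetics (difference-of-exponentials kernel), slow drift and
  additive Gaussian noise.

Bath pH enters through three dials: activation delays shift linearly with
pH, the oscillation initiation rate scales as ``1 + freq_gain*(7.4 - pH)``
and the neighbor-recruitment probability as ``1 - coupling_gain*(7.4 - pH)``.
Acidification therefore speeds up initiation while fragmenting waves, the
combination seen in acidified islets.

Every draw comes from one seeded generator: identical configs give
bit-identical recordings and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial import Delaunay, QhullError

from .core import ConfigurationError, IsletRecording, ProtocolEvent, RoiTrace

__all__ = [
    "SimulationConfig",
    "IsletGeometry",
    "GroundTruth",
    "PlantedEvent",
    "ph_to_h_concentration",
    "ph_to_h_concentration_rounded",
    "generate_geometry",
    "simulate_recording",
    "plant_events",
]


# ---------------------------------------------------------------------------
# pH chemistry
# ---------------------------------------------------------------------------

def ph_to_h_concentration(ph: float) -> float:
    """Free H+ concentration in nM for a given pH.

    [H+] = 10**(-pH) mol/L = 10**(9 - pH) nM.
    """
    if not np.isfinite(ph) or not (0.0 < ph < 14.0):
        raise ValueError(f"pH must be finite and in (0, 14), got {ph!r}")
    return float(10.0 ** (9.0 - ph))


def ph_to_h_concentration_rounded(ph: float) -> int:
    """[H+] rounded to the nearest 10 nM, the convention used for reporting.

    pH 7.1 -> 80 nM, pH 7.4 -> 40 nM, pH 7.7 -> 20 nM.
    """
    return int(round(ph_to_h_concentration(ph) / 10.0) * 10)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsletGeometry:
    """Cell positions in an optical section and the spatial neighbor relation.

    ``neighbor_pairs`` holds unordered index pairs (i < j); the relation is
    symmetric and irreflexive and the neighbor graph is connected.
    """

    positions: np.ndarray  # (n, 2), length units (um)
    neighbor_pairs: frozenset[tuple[int, int]]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def neighbors_of(self, i: int) -> list[int]:
        out = []
        for a, b in self.neighbor_pairs:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_cells)]
        for a, b in self.neighbor_pairs:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def mean_neighbor_count(self) -> float:
        return 2.0 * len(self.neighbor_pairs) / self.n_cells


def _is_connected(n: int, pairs: frozenset[tuple[int, int]]) -> bool:
    if n == 1:
        return True
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    seen = {0}
    stack = [0]
    while stack:
        c = stack.pop()
        for nb in adj[c]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def _blue_noise_ellipse(
    n: int, a: float, b: float, min_dist: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Minimum-distance rejection sampling inside an ellipse; None if stuck."""
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * n
    while len(pts) < n and attempts < max_attempts:
        attempts += 1
        p = rng.uniform([-a, -b], [a, b])
        if (p[0] / a) ** 2 + (p[1] / b) ** 2 > 1.0:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_dist:
            continue
        pts.append(p)
    if len(pts) < n:
        return None
    return np.array(pts)


def generate_geometry(
    n_cells: int,
    field_radius: float = 100.0,
    seed: int = 0,
    *,
    aspect: float = 0.75,
    prune_factor: float = 1.8,
    min_distance: float | None = None,
) -> IsletGeometry:
    """Place ``n_cells`` cells in an elliptical islet section and wire neighbors.

    Positions come from blue-noise (minimum-distance) rejection sampling in an
    ellipse with semi-axes ``field_radius`` and ``aspect * field_radius``.
    Neighbors are Delaunay edges shorter than ``prune_factor`` times the
    median edge length (pruning removes the long sliver edges along the
    convex hull). Sampling repeats with fresh sub-seeds until the pruned
    graph is connected. Deterministic for a fixed seed.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    a, b = float(field_radius), float(aspect * field_radius)
    area = math.pi * a * b
    min_dist = (
        float(min_distance) if min_distance is not None else 0.65 * math.sqrt(area / n_cells)
    )
    # hexagonal packing capacity ~ 1.15 * area / d^2
    if n_cells > 1.15 * area / min_dist**2:
        raise ConfigurationError(
            f"cannot place {n_cells} cells with spacing {min_dist:.1f} in the field"
        )
    rng = np.random.default_rng(seed)
    for _ in range(50):
        pts = _blue_noise_ellipse(n_cells, a, b, min_dist, rng)
        if pts is None:
            continue
        if n_cells == 2:
            return IsletGeometry(pts, frozenset({(0, 1)}))
        try:
            tri = Delaunay(pts)
        except QhullError:
            continue
        edges: set[tuple[int, int]] = set()
        for simplex in tri.simplices:
            for k in range(3):
                i, j = int(simplex[k]), int(simplex[(k + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        lengths = {e: float(np.linalg.norm(pts[e[0]] - pts[e[1]])) for e in edges}
        cutoff = prune_factor * float(np.median(list(lengths.values())))
        pruned = frozenset(e for e, l in lengths.items() if l <= cutoff)
        if _is_connected(n_cells, pruned):
            return IsletGeometry(pts, pruned)
    raise ConfigurationError("failed to generate a connected islet geometry")


# ---------------------------------------------------------------------------
# Simulation config and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All dials of the synthetic islet; defaults are the pH 7.4 scenario.

    Rates: ``plateau_freq`` is the per-cell Poisson rate (events/min) at
    which an activated cell *initiates* an oscillation; the observed per-ROI
    event rate is emergent, roughly ``plateau_freq`` times the mean cascade
    size, which with the defaults lands in the few-per-minute range typical
    of plateau-phase oscillations.
    """

    n_cells: int = 80
    field_radius: float = 100.0          # um
    sampling_rate: float = 10.0          # Hz
    duration: float = 1800.0             # s
    stim_onset: float = 600.0            # s, 6 -> 8 mM glucose step
    ph_protocol: tuple[tuple[float, float], ...] = ((0.0, 7.4),)
    base_delay_mean: float = 400.0       # s, activation delay at pH 7.4
    base_delay_sd: float = 100.0         # s
    delay_shift_per_ph_unit: float = -667.0  # s per pH unit (acidic -> earlier)
    prestim_active_fraction: float = 0.0
    plateau_freq: float = 0.04           # initiations/min per cell at pH 7.4
    freq_gain_per_ph_unit: float = 2.0   # relative rate change per pH unit
    coupling_prob: float = 0.9           # neighbor recruitment prob at pH 7.4
    coupling_gain_per_ph_unit: float = 1.2
    hop_time: float = 0.1                # s per propagation step
    refractory: float = 2.0              # s
    kernel_rise: float = 0.5             # s
    kernel_decay: float = 3.0            # s
    spike_amplitude: float = 1.0         # fluorescence units per oscillation
    activation_step_amplitude: float = 1.0  # sustained plateau elevation
    noise_sd: float = 0.1                # fluorescence units
    drift_amplitude: float = 0.2         # fluorescence units
    drift_period: float = 400.0          # s
    seed: int = 0

    def validate(self) -> None:
        if not (self.sampling_rate > 0):
            raise ConfigurationError("sampling_rate must be > 0")
        if not (self.duration > self.stim_onset >= 0):
            raise ConfigurationError("need duration > stim_onset >= 0")
        if not (0.0 <= self.prestim_active_fraction <= 1.0):
            raise ConfigurationError("prestim_active_fraction must be in [0, 1]")
        if not (0.0 <= self.coupling_prob <= 1.0):
            raise ConfigurationError("coupling_prob must be in [0, 1]")
        if not self.ph_protocol:
            raise ConfigurationError("ph_protocol must have at least one segment")
        starts = [s for s, _ in self.ph_protocol]
        if starts[0] != 0.0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError(
                "ph_protocol segments must start at 0 and be strictly ordered"
            )
        if starts[-1] >= self.duration:
            raise ConfigurationError("ph_protocol segment starts beyond duration")
        if not (0 < self.kernel_rise < self.kernel_decay):
            raise ConfigurationError("need 0 < kernel_rise < kernel_decay")
        if not (0 < self.hop_time <= self.refractory):
            raise ConfigurationError("need 0 < hop_time <= refractory")
        lam_max = max(self.initiation_rate(ph) for _, ph in self.ph_protocol)
        if lam_max * self.refractory > 1.0:
            raise ConfigurationError(
                "initiation rate implies > 1 expected event per refractory period"
            )

    def ph_at(self, t: float) -> float:
        ph = self.ph_protocol[0][1]
        for start, value in self.ph_protocol:
            if t >= start:
                ph = value
            else:
                break
        return ph

    def initiation_rate(self, ph: float) -> float:
        """Per-cell oscillation initiation rate (1/s) at bath pH ``ph``."""
        rate = self.plateau_freq / 60.0 * (1.0 + self.freq_gain_per_ph_unit * (7.4 - ph))
        return max(0.0, rate)

    def recruitment_prob(self, ph: float) -> float:
        """Neighbor recruitment probability at bath pH ``ph``, clipped to [0, 1]."""
        p = self.coupling_prob * (1.0 - self.coupling_gain_per_ph_unit * (7.4 - ph))
        return float(np.clip(p, 0.0, 1.0))


@dataclass
class GroundTruth:
    """Planted truth of one simulated recording.

    ``wave_membership`` maps (cell index, spike index within that cell) to
    the wave id of the cascade the spike belongs to; wave ids partition all
    spikes. ``initiating_cell`` records which cell started each wave.
    """

    activation_time: np.ndarray            # (n_cells,), s
    spike_times: list[np.ndarray]          # per cell, sorted, s
    wave_membership: dict[tuple[int, int], int]
    initiating_cell: dict[int, int] = field(default_factory=dict)
    initiation_time: dict[int, float] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.activation_time.size

    @property
    def n_waves(self) -> int:
        return len(set(self.wave_membership.values()))

    def wave_cells(self) -> dict[int, set[int]]:
        """Participating cell set per wave id."""
        out: dict[int, set[int]] = {}
        for (cell, _), wid in self.wave_membership.items():
            out.setdefault(wid, set()).add(cell)
        return out

    def wave_sizes(self) -> dict[int, int]:
        return {wid: len(cells) for wid, cells in self.wave_cells().items()}

    def n_initiations(self) -> int:
        return len(self.initiating_cell)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _pick_prestim_clusters(
    geometry: IsletGeometry, n_premature: int, rng: np.random.Generator
) -> set[int]:
    """Choose ~4-cell contiguous clusters by BFS growth from random seeds."""
    chosen: set[int] = set()
    adj = geometry.adjacency()
    while len(chosen) < n_premature:
        free = [i for i in range(geometry.n_cells) if i not in chosen]
        seed_cell = int(rng.choice(free))
        frontier = [seed_cell]
        target = min(n_premature - len(chosen), 4)
        grown = 0
        while frontier and grown < target:
            c = frontier.pop(0)
            if c in chosen:
                continue
            chosen.add(c)
            grown += 1
            nbs = [n for n in adj[c] if n not in chosen]
            rng.shuffle(nbs)
            frontier.extend(nbs)
    return chosen


def _draw_initiations(
    config: SimulationConfig, start: float, rng: np.random.Generator
) -> list[float]:
    """Poisson arrivals on [start, duration) with piecewise-constant pH rate."""
    times: list[float] = []
    bounds = [s for s, _ in config.ph_protocol] + [config.duration]
    for (seg_start, ph), seg_end in zip(config.ph_protocol, bounds[1:]):
        lo, hi = max(start, seg_start), seg_end
        if hi <= lo:
            continue
        rate = config.initiation_rate(ph)
        if rate <= 0:
            continue
        t = lo
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= hi:
                break
            times.append(t)
    return times


def _indicator_kernel(config: SimulationConfig) -> np.ndarray:
    """Difference-of-exponentials Ca2+ indicator kernel, peak-normalized."""
    fs = config.sampling_rate
    length = int(round(8.0 * config.kernel_decay * fs)) + 1
    t = np.arange(length) / fs
    k = np.exp(-t / config.kernel_decay) - np.exp(-t / config.kernel_rise)
    peak = k.max()
    if peak <= 0:
        raise ConfigurationError("degenerate indicator kernel")
    return k / peak


def simulate_recording(
    config: SimulationConfig, geometry: IsletGeometry | None = None
) -> tuple[IsletRecording, GroundTruth]:
    """Simulate one islet recording plus its ground truth.

    Model stages:

    1. activation times — ``stim_onset + max(0, N(mu, sd))`` with the mean
       shifted by ``delay_shift_per_ph_unit * (pH - 7.4)``; a binomial draw of
       ``prestim_active_fraction`` cells (contiguous clusters) is instead
       active before the step;
    2. each activated cell initiates oscillations as a Poisson process whose
       rate follows the bath pH at initiation time;
    3. each initiation triggers a cascade over the neighbor graph: every
       untriggered, activated, non-refractory neighbor fires with the
       pH-dependent recruitment probability one hop time later; all spikes of
       a cascade share a wave id;
    4. spike trains are convolved with the indicator kernel; a smooth
       sustained step marks activation; sinusoidal drift and Gaussian noise
       are added.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if geometry is None:
        geometry = generate_geometry(
            config.n_cells, config.field_radius, seed=int(rng.integers(2**31))
        )
    n = geometry.n_cells
    adj = geometry.adjacency()

    # -- stage 1: activation times ------------------------------------------
    ph_stim = config.ph_at(config.stim_onset)
    # negative shift => shorter delays under acidification (left shift)
    mu = config.base_delay_mean + config.delay_shift_per_ph_unit * (7.4 - ph_stim)
    delays = np.maximum(0.0, rng.normal(mu, config.base_delay_sd, size=n))
    activation = config.stim_onset + delays
    n_premature = rng.binomial(n, config.prestim_active_fraction)
    premature = _pick_prestim_clusters(geometry, n_premature, rng) if n_premature else set()
    for cell in sorted(premature):
        if config.stim_onset > 0:
            activation[cell] = rng.uniform(0.5, 0.95) * config.stim_onset
        else:
            activation[cell] = 0.0

    # -- stages 2-3: initiations and cascades -------------------------------
    candidates: list[tuple[float, int]] = []
    for cell in range(n):
        for t in _draw_initiations(config, activation[cell], rng):
            candidates.append((t, cell))
    candidates.sort()

    last_spike = np.full(n, -np.inf)
    spikes: list[list[float]] = [[] for _ in range(n)]
    membership: dict[tuple[int, int], int] = {}
    initiating_cell: dict[int, int] = {}
    initiation_time: dict[int, float] = {}
    next_wave = 0
    for t0, cell in candidates:
        if t0 - last_spike[cell] < config.refractory:
            continue
        wid = next_wave
        next_wave += 1
        p = config.recruitment_prob(config.ph_at(t0))
        fired: dict[int, float] = {cell: t0}
        frontier = [(cell, t0)]
        while frontier:
            c, tc = frontier.pop(0)
            t_next = tc + config.hop_time
            for nb in adj[c]:
                if nb in fired:
                    continue
                if activation[nb] > t_next:
                    continue
                if t_next - last_spike[nb] < config.refractory:
                    continue
                if rng.random() < p:
                    fired[nb] = t_next
                    frontier.append((nb, t_next))
        for c, tc in fired.items():
            membership[(c, len(spikes[c]))] = wid
            spikes[c].append(tc)
            last_spike[c] = tc
        initiating_cell[wid] = cell
        initiation_time[wid] = t0

    spike_arrays = [np.asarray(s, dtype=float) for s in spikes]

    # -- stage 4: fluorescence synthesis ------------------------------------
    n_samples = int(round(config.duration * config.sampling_rate))
    t_grid = np.arange(n_samples) / config.sampling_rate
    kernel = _indicator_kernel(config)
    deltas = np.zeros((n, n_samples))
    for cell in range(n):
        idx = np.round(np.asarray(spikes[cell]) * config.sampling_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_samples)]
        np.add.at(deltas[cell], idx, config.spike_amplitude)
    if deltas.any():
        traces = sps.fftconvolve(deltas, kernel[None, :], axes=-1)[:, :n_samples]
    else:
        traces = deltas
    # sustained plateau elevation switching on at activation (~1 s rise)
    step = 0.5 * (1.0 + np.tanh((t_grid[None, :] - activation[:, None]) / 1.0))
    traces = traces + config.activation_step_amplitude * step
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    traces = traces + config.drift_amplitude * np.sin(
        2.0 * np.pi * t_grid[None, :] / config.drift_period + phases[:, None]
    )
    traces = traces + rng.normal(0.0, config.noise_sd, size=traces.shape) + 1.0

    width = len(str(n - 1))
    roi_ids = [f"roi{idx:0{width}d}" for idx in range(n)]
    recording = IsletRecording(
        traces=[
            RoiTrace(roi_ids[i], traces[i], config.sampling_rate) for i in range(n)
        ],
        positions={
            roi_ids[i]: (float(geometry.positions[i, 0]), float(geometry.positions[i, 1]))
            for i in range(n)
        },
        protocol=_build_protocol(config),
    )
    truth = GroundTruth(
        activation_time=activation,
        spike_times=spike_arrays,
        wave_membership=membership,
        initiating_cell=initiating_cell,
        initiation_time=initiation_time,
    )
    return recording, truth


def _build_protocol(config: SimulationConfig) -> list[ProtocolEvent]:
    events = []
    for start, ph in config.ph_protocol:
        glucose = 8.0 if start >= config.stim_onset else 6.0
        events.append(ProtocolEvent(start_s=float(start), glucose_mM=glucose, ph=float(ph)))
    if config.stim_onset > 0 and all(e.start_s != config.stim_onset for e in events):
        events.append(
            ProtocolEvent(
                start_s=float(config.stim_onset),
                glucose_mM=8.0,
                ph=float(config.ph_at(config.stim_onset)),
            )
        )
    return sorted(events, key=lambda e: e.start_s)


# ---------------------------------------------------------------------------
# Planted-event fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth of one planted Gaussian transient."""

    center_time: float   # s
    amplitude_sd: float  # peak height in units of baseline sd
    fwhm: float          # s


def plant_events(
    n_events: int,
    amplitudes: float | Sequence[float],
    halfwidths: float | Sequence[float],
    baseline_sd: float = 1.0,
    seed: int = 0,
    *,
    sampling_rate: float = 2.0,
    spacing: float | None = None,
    centers: Sequence[float] | None = None,
    margin: float = 30.0,
    roi_id: str = "planted",
) -> tuple[RoiTrace, list[PlantedEvent]]:
    """White-noise baseline with Gaussian transients of known truth.

    ``amplitudes`` are peak heights in units of the baseline sd; ``halfwidths``
    are FWHM in seconds. Scalars broadcast over all events. Events are placed
    ``spacing`` seconds apart (default: 4x the largest FWHM, at least 30 s)
    unless explicit ``centers`` are given; centers closer than the largest
    FWHM are rejected as overlapping.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_events,)).copy()
    fwhms = np.broadcast_to(np.asarray(halfwidths, dtype=float), (n_events,)).copy()
    if n_events and (np.any(amps <= 0) or np.any(fwhms <= 0)):
        raise ValueError("amplitudes and halfwidths must be positive")
    max_fwhm = float(fwhms.max()) if n_events else 0.0
    if centers is None:
        if spacing is None:
            spacing = max(30.0, 4.0 * max_fwhm)
        centers_arr = margin + spacing * np.arange(n_events)
    else:
        centers_arr = np.asarray(centers, dtype=float)
        if centers_arr.size != n_events:
            raise ValueError("centers must match n_events")
    if n_events > 1:
        gaps = np.diff(np.sort(centers_arr))
        if np.any(gaps <= max_fwhm):
            raise ValueError("planted events overlap: separation must exceed the largest halfwidth")

    duration = (centers_arr.max() + margin) if n_events else 2 * margin
    n_samples = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, baseline_sd, size=n_samples)
    t = np.arange(n_samples) / sampling_rate
    truth = []
    for c, a, w in zip(centers_arr, amps, fwhms):
        sigma = w / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        trace += a * baseline_sd * np.exp(-0.5 * ((t - c) / sigma) ** 2)
        truth.append(PlantedEvent(center_time=float(c), amplitude_sd=float(a), fwhm=float(w)))
    return RoiTrace(roi_id, trace, sampling_rate), truth
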