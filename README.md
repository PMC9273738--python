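# isletwave

Analysis of Ca²⁺-imaging recordings from pancreatic islet beta cells:
event detection and activity quantification, glucose-activation timing,
threshold-correlation functional networks, and space-time clustering of
intercellular Ca²⁺ waves — together with a seeded synthetic islet
generator that provides ground truth for validating every stage.

## Who this is for

Beta cells in an islet are gap-junction coupled and respond to a glucose
step with a delayed, staircase-like recruitment followed by a plateau of
repetitive, largely synchronized cytosolic Ca²⁺ ([Ca²⁺]c) oscillations
that propagate between neighbors as intercellular waves. Groups studying
how a modulator (bath pH, glucose level, a drug) reshapes this collective
activity typically quantify four things from ROI-resolved fluorescence
traces: per-cell oscillation statistics, activation delays after the
stimulus, a functional connectivity network, and wave sizes. `isletwave`
implements that pipeline as a tested Python library with a thin CLI.

## The methods at its core

* **Event detection.** Each trace is robustly z-normalized
  (rolling-median detrend; noise scale from first differences) and scanned
  for excursions with z > 4 at a ladder of time scales (0.5–32 s,
  difference-of-boxes band filters with exact white-noise calibration).
  Events carry start time, peak height, halfwidth (FWHM) and AUC; a ROI's
  activity is its summed event AUC per minute, and a ROI is *active* when
  it has more than 10 events.
* **Activation timing.** A cell's activation is the earliest sustained
  rise (z > 3 for ≥ 5 s against a trailing-median baseline) after — or,
  for premature cells, before — the glucose step; delays are reported both
  from the stimulus and from the first activated cell, with
  fraction-active curves over time.
* **Functional networks.** Cells are nodes; an edge joins pairs whose
  band-passed (0.04–2 Hz) traces exceed a Pearson correlation of r > 0.8
  in the analysis window. Coherence is summarized by the average node
  degree 2|E|/N and segregation by the average clustering coefficient
  C̄ = mean over nodes of 2Tᵢ/(kᵢ(kᵢ−1)).
* **Wave clustering.** Band-passed traces are binarized from oscillation
  onset to end (hysteresis + zero-crossing extension with a calibrated
  noise gate); active runs of spatially neighboring cells whose intervals
  overlap within a time tolerance form one wave (connected components of
  the run graph). Wave size is the number of distinct participating cells
  divided by the islet's cell count.
* **Synthetic islets.** Cells are placed by blue-noise sampling in an
  ellipse and wired by pruned Delaunay triangulation. Activation delays
  are Gaussian with a pH-dependent shift; oscillations start as per-cell
  Poisson initiations and spread as stochastic cascades over the neighbor
  graph with pH-dependent recruitment probability; spike trains are
  convolved with an indicator kernel and corrupted with drift and noise.
  The generator returns the exact ground truth (activation times, spike
  times, wave membership).

## Worked example

```python
import numpy as np
import isletwave as iw

cfg = iw.SimulationConfig(seed=1)            # 80 cells, 30 min, step at 600 s
recording, truth = iw.simulate_recording(cfg)

profile = iw.build_activation_profile(recording, stimulus_onset=cfg.stim_onset)
print(profile.table["delay_from_stimulus"].median())

corr, ids = iw.correlation_matrix(recording, window=(1200.0, 1800.0))
net = iw.build_network(corr, ids, positions=recording.positions)
print(iw.average_node_degree(net), iw.average_clustering_coefficient(net))
```

Running `python examples/01_simulate_islet.py` prints

```
80 cells, 1800 s at 10 Hz
mean activation delay: 393 s (configured 400 s)
34 intercellular waves; mean size 74.6 of 80 cells (pH 7.4 coupling gives near-global waves)
spikes per cell: median 32
```

i.e. the analysis recovers the 400 s recruitment delay the generator
planted, and at control-pH coupling nearly every oscillation engages the
whole islet. `examples/04_functional_network.py` contrasts matched
recordings at pH 7.4 and 7.1:

```
pH 7.4: N=80  edges=3160  avg degree=79.0  avg clustering=1.000
pH 7.1: N=80  edges=2585  avg degree=64.6  avg clustering=0.895
```

— acidification speeds up oscillations but fragments the functional
network, the signature this pipeline is built to quantify. The other
examples cover event detection on planted transients, activation timing
with premature clusters, wave-size distributions, and the full per-epoch
pipeline (`isletwave run` on the command line).

## Layout

```
src/isletwave/
  core.py        traces, recordings, shared containers
  synthetic.py   geometry, simulator, planted-event fixtures, pH chemistry
  events.py      normalization, multi-scale event detection, activity
  activation.py  activation times, delays, active-fraction curves
  network.py     correlation networks, degree, clustering
  waves.py       band-pass, binarization, space-time wave clustering
  scenarios.py   end-to-end validation scenarios
  pipeline.py    per-epoch orchestration, reports
  io.py          delimited-text / YAML / JSON readers and writers
  plotting.py    network, raster and activation figures
  cli.py         `isletwave simulate|events|activation|network|waves|run`
```
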