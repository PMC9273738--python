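# Methods

This note documents the models, estimators and numerical choices behind
`isletwave`, and what validation on synthetic data does and does not
establish about real recordings.

## The synthetic islet

The generator is a phenomenological model of a glucose-stimulated beta-cell
collective, built to reproduce the *statistical structure* the analysis
assumes — not the biophysics. It has four layers.

**Geometry.** `n_cells` (default 80, a typical ROI count in one islet
optical section) are placed by minimum-distance rejection sampling inside
an ellipse of semi-axes `field_radius` × 0.75·`field_radius` (default
100 µm). Neighbors are Delaunay edges no longer than 1.8× the median edge
length; sampling repeats until the pruned graph is connected. Mean
neighbor count lands near 5, consistent with packed cells in a plane.
When only ROI coordinates are available (real data), adjacency instead
joins all pairs closer than 2× the median nearest-neighbor distance.

**Recruitment.** Each cell activates at
`stim_onset + max(0, N(μ, σ))` with `μ = base_delay_mean +
delay_shift_per_ph_unit · (7.4 − pH)` and `σ = base_delay_sd` (defaults
400 s, 100 s). `delay_shift_per_ph_unit = −667 s/pH` places the pH 7.1
mean delay near 200 s — acidification left-shifts recruitment. A
binomially drawn fraction `prestim_active_fraction` of cells is active
before the step; they are chosen as contiguous ~4-cell clusters grown by
breadth-first search, because premature activity appears as small spatial
clusters, and their activation times are uniform in [0.5, 0.95]·
`stim_onset`. On activation a cell's baseline rises by
`activation_step_amplitude` (smooth ~1 s step): the plateau phase sits on
an elevated pedestal, which is also what makes onset detection by a
sustain criterion possible.

**Oscillations and waves.** After activation a cell initiates oscillation
events as a Poisson process with rate
`plateau_freq · (1 + freq_gain_per_ph_unit · (7.4 − pH))` (per minute);
each initiation starts a cascade over the neighbor graph in which every
untriggered, activated, non-refractory neighbor fires with probability
`coupling_prob · (1 − coupling_gain_per_ph_unit · (7.4 − pH))` (clipped
to [0, 1]) one `hop_time` later. All spikes of a cascade share a wave id;
a cell cannot re-fire within `refractory` seconds. Defaults: hop 0.1 s
(an 80-cell islet is traversed in ≲1 s, so waves look near-simultaneous
at 2 Hz imaging), refractory 2 s (oscillations stay distinguishable),
`plateau_freq` 0.04 min⁻¹ per cell. The *observed* per-ROI rate is
emergent — roughly initiation rate × mean cascade size — and sits near
2.5–3 events/min at pH 7.4; higher initiation rates saturate the islet
because every near-global wave puts all cells into refractory together.

**Fluorescence.** Spike trains are convolved with a peak-normalized
difference of exponentials (rise 0.5 s, decay 3 s — calcium-indicator
kinetics), then the activation pedestal, a sinusoidal drift
(amplitude 0.2, period 400 s) and white Gaussian noise (sd 0.1; spike
amplitude 1.0, so SNR ≈ 10) are added. Photon-shot statistics are
deliberately out of scope.

**pH calibration.** The two pH gains are calibrated once to the
magnitudes reported for acidification of islets by 0.3 pH units:
`freq_gain_per_ph_unit = 2.0` makes the *emergent observed* frequency
increase at pH 7.1 (initiation gain, damped by refractory dead time and
slightly smaller cascades) land near +40%, and
`coupling_gain_per_ph_unit = 1.2` lowers recruitment from 0.90 to ≈ 0.58,
fragmenting waves and the functional network without extinguishing
synchrony. The response is linear in pH, so the model cannot
simultaneously express a strong acid effect and a null alkaline effect;
at pH 7.7 it predicts a frequency *decrease*, which real islets do not
show. Directional comparisons in the test suite therefore use the
7.1-vs-7.4 contrast only.

## Event detection

Traces are normalized as `(x − rolling_median(x)) / s`. The median window
(default 120 s, centered) must exceed twice the broadest event support
(a 20 s-FWHM event spans ~50 s), or wide events are clipped and their
widths biased low. The scale `s` is the robust sd of first differences
divided by √2: transients are smooth sample-to-sample while noise is not,
so the estimate stays anchored to the noise floor even when oscillations
fill the trace — a plain MAD of the samples would absorb signal and
silently desensitize the detector in exactly the recordings that matter.

Detection scans a geometric ladder of scales (0.5–32 s; bounded below by
the sampling interval and above by the slow-drift regime that the wave
band-pass's 0.04 Hz corner excludes). Each scale applies a
difference-of-boxes band filter — box mean over `w` samples minus box
mean over `4w` — renormalized by its exact white-noise sd `√(3/(4w))`.
The wide box subtracts the local pedestal, so a dense periodic train
remains resolved into individual oscillations at every scale; a single
rescaled box average would fuse it into one broad excursion. Excursions
above z = 4 become candidates; candidates from different scales whose
half-height intervals overlap are resolved greedily toward the highest
smoothed z (deterministic tie-break by position). Each survivor is then
measured on the unsmoothed normalized trace:

* *peak height*: the raw maximum in the candidate interval (must itself
  exceed the threshold, or the candidate is dropped);
* *half level*: half of a 3-point median at the peak — the raw maximum
  overestimates amplitude by the noise extreme, which would bias widths
  narrow;
* *halfwidth*: occupancy above the half level within the event support,
  divided by the sampling rate. Under symmetric noise, early and late
  crossings cancel, making this estimator unbiased where walking to the
  first sub-half sample is biased narrow on shallow flanks. Mean absolute
  relative error on planted Gaussians (FWHM 2–20 s, 2 Hz sampling) is
  ≈ 9%; individual 2 s events carry ±0.25 s sampling granularity.
* *start time*: the last sub-half-level sample before the peak;
* *AUC*: trapezoidal area of the positive part over the support, which
  extends from the half-height bounds to the surrounding baseline
  crossings, capped at midpoints to adjacent events.

Activity per ROI is events/min and ΣAUC/min; `is_active` requires
strictly more than 10 events ("more than 10" read literally). Summaries
of non-negative quantities (AUC, halfwidth, rate) are computed on the
natural-log scale with zeros excluded and counted.

## Activation timing

Onset detection needs a *causal* baseline: a centered rolling median
absorbs a sustained step within a few samples, leaving nothing to detect.
`causal_normalize` therefore uses a trailing 120 s median, under which a
step stays elevated for about half the window. Activation is the earliest
time the causal z-trace exceeds 3 continuously for 5 s (both
configurable; a manual-override table per ROI is accepted). Searching
from t = 0 makes premature activation visible as negative delays.
Non-responders are excluded from delay statistics but kept in the
denominator of the active-fraction curve; both denominator conventions
are available (`include_nonresponders`). On default synthetic recordings
the detector is accurate to ≲1 s per cell, and pooled recovery of the
configured 400 s mean delay is within a few seconds.

## Functional networks

Pairwise Pearson correlation is computed on band-passed (0.04–2 Hz)
traces by default so drift and the shared plateau pedestal cannot inflate
it; a raw mode exists. Windows shorter than 60 s are refused; a constant
trace gets zeroed correlations and a warning. Edges require r > 0.8
strictly. All ROIs remain nodes (degree 0 allowed) so metrics are
comparable across epochs at fixed N. Average node degree is 2|E|/N;
average clustering uses the standard local coefficient with C = 0 for
degree < 2. The suite verifies the clustering value against an exhaustive
triple-enumeration oracle on random graphs.

## Wave extraction

The fast component is isolated with a zero-phase (forward–backward)
2nd-order Butterworth band-pass, 0.04–2 Hz. An upper corner at or above
Nyquist is clipped to 0.99× Nyquist with a warning — at 2 Hz acquisition
the literal 2 Hz corner is unrealizable, which is also why the simulator
samples at 10 Hz, where the full band is exercisable. Each
`bandpass_filter` call carries a calibration constant for its filter: the
ratio of filtered-white-noise sd to the sd of its first differences,
measured once on a long fixed-seed noise record. Binarization uses it to
convert the (signal-insensitive) diff-based noise estimate into the
band-limited noise floor.

Binarization is hysteresis thresholding on the filtered trace scaled by
its own robust sd: a run turns on above θ_on = 2, extends backward to the
preceding zero crossing (the onset) and forward to the first zero
crossing after dropping below θ_off = 0.5 (the end) — runs literally span
onset to end of each oscillation. A run is kept only if its peak exceeds
5× the calibrated noise sd; without this gate, filter sidelobes and noise
excursions become sporadic runs that appear as spurious single-cell
waves. At 5σ a pure-noise run survives less than once per ~3 h of trace.

Waves are connected components of the run graph: two runs connect when
their cells are spatial neighbors (or the same cell) and their intervals,
each dilated by `time_tolerance`/2 (default 1 s ≥ hop time), overlap. The
partition covers every active sample; an isolated run is a size-1 wave.
Relative size is distinct participating cells over islet cell count —
duration is reported separately, never folded into the size scalar. The
implementation (networkx components) is checked exactly against a
hand-written union–find oracle on random grids.

## Pipeline conventions

Per-epoch analysis skips the first 60 s after every solution switch
(bath exchange and filter edge transients); validation scenarios also
drop waves truncated by an analysis-window edge. Events are detected once
on full-length traces and assigned to epochs by peak time, so epoch
boundaries cannot split an event. A fixed seed makes the entire run —
simulation, analysis, summary digest — bit-reproducible.

## What the synthetic validation shows — and what it does not

Passing tests establish that each estimator recovers what the generator
planted (delays, premature fraction, spike/run counts, wave membership)
and that the full chain reproduces the *direction* of the acidification
phenotype: higher event rate, lower average node degree and clustering,
smaller median wave size at pH 7.1 than at matched pH 7.4 recordings.
They do not establish magnitudes for real tissue: the generator's
coupling parameters are fixtures, its noise is white and Gaussian, ROI
traces contain no motion artifacts or crosstalk, and the pH response is
linearized. The constant-pH control scenario (90 min) shows event-rate
ratios between recording thirds near 1, but because initiations are
Poisson at the islet level, individual 30-min thirds still fluctuate by
~15%.

## Scenario sizes

Validation uses 80-cell islets with 20-min plateau epochs for the pH
contrasts (5 matched seed pairs), 30-min step recordings for delay and
premature-fraction recovery (5–10 seeds), 90-min controls (5 seeds), and
12-cell low-rate islets for the exact coupling-limit checks, where long
refractory periods and short kernels keep cascades temporally isolated —
the regime in which detected and ground-truth partitions can be compared
exactly.
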