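"""Detect [Ca2+]c events in a noisy trace with planted ground truth.

Plants 20 Gaussian transients of known amplitude and width into white
noise, normalizes, detects events at z > 4 across the scale ladder, and
compares the recovered halfwidths with the planted truth.
"""

import numpy as np

import isletwave as iw

rng = np.random.default_rng(0)
amps = rng.uniform(6, 10, 20)       # peak heights, in baseline-sd units
fwhms = rng.uniform(2, 20, 20)      # widths at half amplitude, seconds
trace, truth = iw.plant_events(20, amps, fwhms, baseline_sd=0.5, seed=1,
                               sampling_rate=2.0, spacing=80.0)

z = iw.normalize_trace(trace)
events = iw.detect_events(z, z_threshold=4.0)
activity = iw.compute_activity(events, duration=trace.duration)

print(f"planted {len(truth)} events, detected {len(events)}")
err = [abs(e.halfwidth - p.fwhm) / p.fwhm
       for p, e in zip(truth, sorted(events, key=lambda e: e.peak_time))]
print(f"mean halfwidth error: {100 * np.mean(err):.1f}%  (events carry start, "
      "peak height, halfwidth, AUC)")
print(activity.round(3))
print("a ROI is 'active' once it carries more than 10 events")
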