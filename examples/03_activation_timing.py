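"""Measure glucose-step activation delays, including premature cells.

Simulates an acidic (pH 7.1) islet where ~10% of cells activate already
at basal glucose, then recovers per-cell delays and the premature
fraction from the fluorescence alone.
"""

import numpy as np

import isletwave as iw

cfg = iw.SimulationConfig(prestim_active_fraction=0.10,
                          ph_protocol=((0.0, 7.1),), seed=4)
recording, truth = iw.simulate_recording(cfg)

profile = iw.build_activation_profile(recording, stimulus_onset=cfg.stim_onset)
grid = np.linspace(0, recording.duration, 200)
frac = iw.active_fraction_curve(profile, grid)

print(f"responders: {profile.n_responders}, non-responders: {profile.n_nonresponders}")
print(f"median delay from stimulus: "
      f"{profile.table['delay_from_stimulus'].median():.0f} s "
      "(acidification shifts the ~400 s control delay to ~200 s)")
print(f"premature fraction: {iw.premature_fraction(profile):.3f} (configured 0.10)")
print(f"half the islet is active by t = {grid[np.searchsorted(frac, 0.5)]:.0f} s")
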