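"""Extract intercellular Ca2+ waves by space-time clustering.

Band-pass each trace to the fast oscillation band, binarize oscillations
from onset to end, and cluster active runs of neighboring cells into
waves. Wave size is reported relative to the islet (cells involved / N).
"""

import numpy as np

import isletwave as iw
from isletwave.pipeline import _geometry_from_positions
from isletwave.scenarios import plateau_config

segs = {}
for ph in (7.4, 7.1):
    cfg = plateau_config(ph, seed=12, minutes=20.0)
    recording, _ = iw.simulate_recording(cfg)
    geometry = _geometry_from_positions(recording)
    windowed = recording.window(60.0, recording.duration)
    filtered = [iw.bandpass_filter(t, low=0.04, high=2.0) for t in windowed.traces]
    binary = iw.binarize_recording(filtered)
    segs[f"pH {ph}"] = iw.segment_waves(binary, geometry, time_tolerance=1.0)

summary = iw.wave_size_distribution(segs)
print(summary.round(3))
print("median relative size near 1 = predominantly global waves;"
      " acidification shrinks and fragments them")

raster = iw.raster_export(
    iw.binarize_recording(
        [iw.bandpass_filter(t) for t in recording.window(60, 360).traces]
    ),
    iw.segment_waves(
        iw.binarize_recording(
            [iw.bandpass_filter(t) for t in recording.window(60, 360).traces]
        ),
        geometry,
    ),
)
print(f"raster table: {len(raster)} active samples across "
      f"{raster['wave_id'].nunique()} waves in a 5 min excerpt")
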