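import numpy as np
import pytest

import isletwave as iw


@pytest.fixture(scope="session")
def plateau_sim():
    """Plateau-only recording at pH 7.4: all cells active from t=0."""
    cfg = iw.SimulationConfig(
        n_cells=40,
        duration=1200.0,
        stim_onset=0.0,
        base_delay_mean=0.0,
        base_delay_sd=0.0,
        seed=11,
    )
    rec, truth = iw.simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def step_sim():
    """Glucose-step recording with the default 400 s delay distribution."""
    cfg = iw.SimulationConfig(n_cells=40, seed=7)
    rec, truth = iw.simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def planted_fixture():
    """100 planted Gaussian transients (peak 6-10 sd, FWHM 2-20 s, 2 Hz)."""
    rng = np.random.default_rng(42)
    amps = rng.uniform(6.0, 10.0, 100)
    fwhms = rng.uniform(2.0, 20.0, 100)
    trace, truth = iw.plant_events(
        100, amps, fwhms, baseline_sd=0.5, seed=43, sampling_rate=2.0, spacing=80.0
    )
    return trace, truth


def match_events(detected, truth):
    """Greedy 1-1 match of detected events to planted truth by peak time."""
    matches = []
    used = set()
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
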