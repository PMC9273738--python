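"""Band-pass filtering, binarization, and space-time wave clustering."""

import numpy as np
import pytest

import isletwave as iw
from isletwave.core import RoiTrace
from isletwave.synthetic import IsletGeometry


def _geometry(n):
    return iw.generate_geometry(n, 100.0, seed=17)


def _union_find_oracle(binary, geometry, time_tolerance):
    """Brute-force reference: union-find over all run pairs."""
    fs = binary.sampling_rate
    half = time_tolerance / 2.0
    nodes = []
    intervals = {}
    for ci, rid in enumerate(binary.roi_ids):
        for ri, (s, e) in enumerate(binary.runs(rid)):
            nodes.append((ci, rid, ri))
            intervals[(rid, ri)] = (s / fs - half, e / fs + half)
    parent = {node[1:]: node[1:] for node in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    neighbor = set(geometry.neighbor_pairs)
    for i, (ci, rid_i, ri) in enumerate(nodes):
        for cj, rid_j, rj in nodes[i + 1:]:
            pair = (min(ci, cj), max(ci, cj))
            if ci != cj and pair not in neighbor:
                continue
            s1, e1 = intervals[(rid_i, ri)]
            s2, e2 = intervals[(rid_j, rj)]
            if s1 < e2 and s2 < e1:
                union((rid_i, ri), (rid_j, rj))
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def _partition(seg):
    groups = {}
    for node, wid in seg.labels.items():
        groups.setdefault(wid, set()).add(node)
    return {frozenset(g) for g in groups.values()}


class TestBandpassFilter:
    def test_constant_trace_rejected_to_zero(self):
        tr = RoiTrace("c", np.full(4000, 5.0), 10.0)
        out = iw.bandpass_filter(tr)
        assert np.max(np.abs(out.samples)) < 1e-8 * 5.0

    def test_passband_sine_amplitude_preserved(self):
        t = np.arange(6000) / 10.0
        tr = RoiTrace("s", np.sin(2 * np.pi * 0.2 * t), 10.0)
        out = iw.bandpass_filter(tr, low=0.04, high=2.0)
        mid = out.samples[1000:-1000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_sine_strongly_attenuated(self):
        t = np.arange(12000) / 10.0
        tr = RoiTrace("s", np.sin(2 * np.pi * 0.005 * t), 10.0)
        out = iw.bandpass_filter(tr, low=0.04, high=2.0)
        assert np.max(np.abs(out.samples[2000:-2000])) < 0.2

    def test_upper_corner_clipped_to_nyquist_with_warning(self):
        rng = np.random.default_rng(0)
        tr = RoiTrace("n", rng.normal(0, 1, 1000), 2.0)
        with pytest.warns(UserWarning, match="Nyquist"):
            iw.bandpass_filter(tr, low=0.04, high=2.0)

    def test_invalid_band_rejected(self):
        tr = RoiTrace("x", np.zeros(100), 10.0)
        with pytest.raises(ValueError):
            iw.bandpass_filter(tr, low=1.0, high=0.5)


class TestBinarize:
    def test_noise_below_threshold_gives_all_zeros(self):
        rng = np.random.default_rng(1)
        tr = RoiTrace("n", rng.normal(0, 1.0, 3000), 10.0)
        filtered = iw.bandpass_filter(tr)
        binary = iw.binarize(filtered)
        # pure noise: the significance gate removes all runs
        assert binary.masks["n"].sum() < 0.02 * 3000

    def test_single_oscillation_single_run_spanning_onset_to_end(self):
        t = np.arange(4000) / 10.0
        pulse = np.exp(-0.5 * ((t - 200.0) / 2.0) ** 2)
        rng = np.random.default_rng(2)
        tr = RoiTrace("p", pulse + rng.normal(0, 0.02, t.size), 10.0)
        binary = iw.binarize(iw.bandpass_filter(tr))
        runs = binary.runs("p")
        assert len(runs) == 1
        s, e = runs[0]
        assert s / 10.0 < 200.0 < e / 10.0

    def test_run_count_tracks_ground_truth_spikes(self):
        # high-SNR, well-separated oscillations: one run per spike
        cfg = iw.SimulationConfig(
            n_cells=20,
            duration=1200.0,
            stim_onset=0.0,
            base_delay_mean=0.0,
            base_delay_sd=0.0,
            plateau_freq=0.06,
            refractory=6.0,
            kernel_decay=1.5,
            noise_sd=0.03,
            seed=23,
        )
        rec, truth = iw.simulate_recording(cfg)
        total_runs, total_spikes = 0, 0
        for i, tr in enumerate(rec.traces):
            binary = iw.binarize(iw.bandpass_filter(tr))
            total_runs += len(binary.runs(tr.roi_id))
            total_spikes += len(truth.spike_times[i])
        assert total_spikes > 0
        assert abs(total_runs - total_spikes) / total_spikes <= 0.10


def _random_binary(n_cells, n_frames, fs, seed, p_on=0.12):
    rng = np.random.default_rng(seed)
    masks = {}
    for i in range(n_cells):
        m = rng.random(n_frames) < p_on
        masks[f"r{i:02d}"] = m
    return iw.BinarizedActivity(masks=masks, sampling_rate=fs)


class TestSegmentWaves:
    def test_single_run_single_wave(self):
        geom = _geometry(5)
        masks = {f"r{i}": np.zeros(100, dtype=bool) for i in range(5)}
        masks["r2"][40:50] = True
        binary = iw.BinarizedActivity(masks=masks, sampling_rate=10.0)
        seg = iw.segment_waves(binary, geom)
        assert seg.n_waves == 1
        assert seg.waves[0].relative_size == pytest.approx(1 / 5)

    def test_partition_matches_union_find_oracle(self):
        geom = _geometry(20)
        for seed in range(100):
            binary = _random_binary(20, 200, 2.0, seed=seed)
            seg = iw.segment_waves(binary, geom, time_tolerance=1.0)
            oracle = _union_find_oracle(binary, geom, time_tolerance=1.0)
            assert _partition(seg) == oracle

    def test_relabeling_cells_preserves_size_multiset(self):
        geom = _geometry(12)
        binary = _random_binary(12, 150, 2.0, seed=3)
        seg = iw.segment_waves(binary, geom)
        perm = np.random.default_rng(4).permutation(12)
        masks2 = {
            f"r{i:02d}": binary.masks[f"r{perm[i]:02d}"] for i in range(12)
        }
        geom2 = IsletGeometry(
            positions=geom.positions[perm],
            neighbor_pairs=frozenset(
                (min(a, b), max(a, b))
                for a, b in (
                    (int(np.where(perm == x)[0][0]), int(np.where(perm == y)[0][0]))
                    for x, y in geom.neighbor_pairs
                )
            ),
        )
        seg2 = iw.segment_waves(
            iw.BinarizedActivity(masks=masks2, sampling_rate=2.0), geom2
        )
        assert sorted(seg.relative_sizes()) == pytest.approx(
            sorted(seg2.relative_sizes())
        )

    def test_larger_tolerance_never_increases_wave_count(self):
        geom = _geometry(15)
        binary = _random_binary(15, 200, 2.0, seed=5, p_on=0.08)
        counts = [
            iw.segment_waves(binary, geom, time_tolerance=tol).n_waves
            for tol in (0.0, 0.5, 1.0, 2.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_relative_sizes_in_unit_interval(self):
        geom = _geometry(10)
        binary = _random_binary(10, 300, 2.0, seed=6)
        seg = iw.segment_waves(binary, geom)
        sizes = seg.relative_sizes()
        assert np.all(sizes > 0.0) and np.all(sizes <= 1.0)

    def test_ground_truth_partition_recovered_for_isolated_cascades(self):
        cfg = iw.SimulationConfig(
            n_cells=12,
            duration=1200.0,
            stim_onset=0.0,
            base_delay_mean=0.0,
            base_delay_sd=0.0,
            plateau_freq=0.05,
            coupling_prob=1.0,
            refractory=8.0,
            kernel_decay=1.5,
            seed=31,
        )
        rec, truth = iw.simulate_recording(cfg)
        from isletwave.pipeline import _geometry_from_positions

        geom = _geometry_from_positions(rec)
        # skip the first 60 s (activation/filter transient), as the
        # pipeline's post-switch exclusion window does
        windowed = rec.window(60.0, rec.duration)
        filtered = [iw.bandpass_filter(t) for t in windowed.traces]
        binary = iw.binarize_recording(filtered)
        seg = iw.segment_waves(binary, geom, time_tolerance=1.0)
        truth_sizes = sorted(
            len(cells)
            for wid, cells in truth.wave_cells().items()
            if truth.initiation_time[wid] >= 60.0
        )
        assert sorted(w.n_cells for w in seg.waves) == truth_sizes


class TestWaveSizeDistribution:
    def _seg_from_sizes(self, sizes, n_cells=10):
        waves = [
            iw.Wave(
                wave_id=k,
                cells=frozenset(f"r{i}" for i in range(int(round(s * n_cells)))),
                runs=((f"r0", k),),
                start_time=0.0,
                end_time=1.0,
                relative_size=s,
            )
            for k, s in enumerate(sizes)
        ]
        return iw.WaveSegmentation(
            waves=waves, labels={}, n_cells_total=n_cells, sampling_rate=10.0
        )

    def test_all_global_waves_have_zero_iqr(self):
        df = iw.wave_size_distribution({"a": self._seg_from_sizes([1.0, 1.0, 1.0])})
        assert df.loc["a", "median"] == 1.0
        assert df.loc["a", "q75"] - df.loc["a", "q25"] == 0.0

    def test_median_of_three_sizes(self):
        df = iw.wave_size_distribution({"a": self._seg_from_sizes([0.2, 0.5, 1.0])})
        assert df.loc["a", "median"] == 0.5

    def test_epoch_without_waves_rejected(self):
        with pytest.raises(ValueError):
            iw.wave_size_distribution({"a": self._seg_from_sizes([])})


class TestRasterExport:
    def test_empty_segmentation_empty_table(self):
        geom = _geometry(4)
        masks = {f"r{i}": np.zeros(50, dtype=bool) for i in range(4)}
        binary = iw.BinarizedActivity(masks=masks, sampling_rate=10.0)
        seg = iw.segment_waves(binary, geom)
        assert iw.raster_export(binary, seg).empty

    def test_wave_ids_and_active_samples_conserved(self):
        geom = _geometry(10)
        binary = _random_binary(10, 200, 2.0, seed=8)
        seg = iw.segment_waves(binary, geom)
        table = iw.raster_export(binary, seg)
        assert len(table) == binary.total_active_samples()
        assert table["wave_id"].nunique() == seg.n_waves
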