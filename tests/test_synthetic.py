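"""Generator contracts: determinism, rate fidelity, coupling and geometry."""
from __future__ import annotations

import numpy as np
import pytest

from zgsync.datatypes import SpikeTrain
from zgsync.synchrony import jaccard_index
from zgsync.synthetic import SynthConfig, generate_frap, generate_recording

from conftest import truth_trains


def baseline_only(n_frames):
    return (("baseline", 0, n_frames, "control"),)


class TestGenerateRecording:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_slices=1, cells_per_slice=8, n_frames=2000, seed=42)
        s1, t1 = generate_recording(cfg)
        s2, t2 = generate_recording(cfg)
        assert np.array_equal(s1.traces.to_numpy(), s2.traces.to_numpy())
        assert t1.coupled_pairs == t2.coupled_pairs
        for cid in s1.cell_ids:
            assert np.array_equal(t1.true_spike_frames[cid], t2.true_spike_frames[cid])

    def test_no_coupling_when_probability_zero(self):
        cfg = SynthConfig(n_slices=2, cells_per_slice=10, n_frames=1000,
                          coupling_prob=0.0, seed=1)
        _, truth = generate_recording(cfg)
        assert truth.coupled_pairs == set()

    def test_example_recording_scale(self):
        """A 14-cell, 45-min session at 10 frames/s has the expected shape."""
        cfg = SynthConfig(n_slices=1, cells_per_slice=14, n_frames=27_000,
                          frame_interval=0.1, seed=0)
        session, _ = generate_recording(cfg)
        assert session.traces.shape == (27_000, 14)
        assert session.n_frames * session.frame_interval == pytest.approx(2700.0)  # 45 min

    def test_baseline_rate_fidelity(self, coupled_session):
        """Ground-truth spiking averages base_rate in the baseline epoch (<5% off)."""
        session, truth = coupled_session
        ep = session.epoch("baseline")
        lead = int(60 / session.frame_interval)
        dur = (ep.end - ep.start - lead) * session.frame_interval
        rates = []
        for frames in truth.true_spike_frames.values():
            kept = frames[(frames >= ep.start + lead) & (frames < ep.end)]
            rates.append(kept.size / dur)
        assert np.mean(rates) == pytest.approx(0.43, rel=0.05)

    def test_coupled_pairs_within_rosette_only(self, coupled_session):
        session, truth = coupled_session
        slice_of = session.slice_of
        for pair in truth.coupled_pairs:
            a, b = sorted(pair)
            assert slice_of[a] == slice_of[b]
            ga, gb = session.geometry[a], session.geometry[b]
            d = np.hypot(ga.center_um[0] - gb.center_um[0],
                         ga.center_um[1] - gb.center_um[1])
            # near neighbours: about one cell spacing apart
            assert d < 2 * truth.config.cell_spacing

    def test_ji_monotone_in_coupling_strength(self):
        """Mean ground-truth JI of coupled pairs grows with coupling_strength."""
        means = []
        for s in (0.2, 0.5, 0.8):
            cfg = SynthConfig(n_slices=1, cells_per_slice=30, n_frames=9000,
                              coupling_prob=0.5, coupling_strength=s,
                              epochs=baseline_only(9000), seed=7)
            _, truth = generate_recording(cfg)
            trains = truth_trains(truth, 9000)
            ji = [jaccard_index(trains[a], trains[b])
                  for a, b in map(sorted, truth.coupled_pairs)]
            means.append(np.mean(ji))
        assert means[0] < means[1] < means[2]

    def test_uncoupled_pairs_at_chance_level(self, small_session):
        """Without coupling every pair's JI stays near the independence level."""
        session, truth = small_session
        trains = truth_trains(truth, session.n_frames)
        ids = session.cell_ids
        n = session.n_frames
        observed, expected = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = trains[ids[i]], trains[ids[j]]
                ji = jaccard_index(a, b)
                assert ji < 0.1
                observed.append(ji)
                expected.append((a.n_spikes * b.n_spikes / n) / (a.n_spikes + b.n_spikes))
        assert np.mean(observed) == pytest.approx(np.mean(expected), abs=0.01)

    def test_geometry_layout(self):
        cfg = SynthConfig(n_slices=1, cells_per_slice=12, rosette_size=6,
                          n_frames=100, seed=0)
        session, _ = generate_recording(cfg)
        ids = session.cell_ids
        centers = {c: np.array(session.geometry[c].center_um) for c in ids}
        # ring neighbours of rosette 0 sit at ~cell_spacing
        d01 = np.linalg.norm(centers[ids[0]] - centers[ids[1]])
        assert d01 == pytest.approx(cfg.cell_spacing, abs=1.0)
        # any cross-rosette pair is much farther apart
        cross = np.linalg.norm(centers[ids[0]] - centers[ids[6]])
        within_max = max(np.linalg.norm(centers[ids[i]] - centers[ids[j]])
                         for i in range(6) for j in range(i + 1, 6))
        assert cross > within_max

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            SynthConfig(n_frames=0)
        with pytest.raises(ValueError):
            SynthConfig(coupling_prob=1.5)
        with pytest.raises(ValueError):
            SynthConfig(base_rate=-1.0)
        with pytest.raises(ValueError):
            SynthConfig(n_slices=2, cells_per_slice=(5,))


class TestGenerateFrap:
    def test_immobile_trace_flat_at_bleach_depth(self):
        cfg = SynthConfig(noise_sd=0.0)
        tr = generate_frap(0.0, 20.0, 0.1, cfg)
        post = tr.intensities[tr.bleach_index:]
        assert np.allclose(post, 0.1 * cfg.baseline_intensity)

    def test_fully_mobile_trace_returns_to_prebleach(self):
        cfg = SynthConfig(noise_sd=0.0)
        tr = generate_frap(1.0, 5.0, 0.1, cfg, duration=200.0)
        assert tr.intensities[-1] == pytest.approx(cfg.baseline_intensity, rel=0.01)

    def test_seed_determinism(self):
        cfg = SynthConfig(noise_sd=3.0)
        a = generate_frap(0.5, 10.0, 0.1, cfg, seed=5)
        b = generate_frap(0.5, 10.0, 0.1, cfg, seed=5)
        assert np.array_equal(a.intensities, b.intensities)

    def test_parameter_validation(self):
        cfg = SynthConfig()
        with pytest.raises(ValueError):
            generate_frap(1.5, 10.0, 0.1, cfg)
        with pytest.raises(ValueError):
            generate_frap(0.5, -1.0, 0.1, cfg)
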