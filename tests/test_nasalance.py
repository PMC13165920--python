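"""Framing, RMS, gating, trajectory, and summary contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasometry import (
    FrameConfig,
    GateConfig,
    compute_trajectory,
    frame_rms,
    frame_signal,
    passthrough,
    summarize,
)
from conftest import SR, make_recording


class TestFraming:
    def test_frame_count_50ms_window_50pct_overlap(self):
        # 1.0 s of signal, 50 ms window, 25 ms hop -> floor((1000-50)/25)+1
        times, frames = frame_signal(np.ones(SR), SR, FrameConfig())
        assert frames.shape[0] == 39

    def test_zero_overlap_tiles_signal(self):
        cfg = FrameConfig(window_s=0.050, overlap_fraction=0.0)
        _, frames = frame_signal(np.ones(SR), SR, cfg)
        assert frames.shape[0] == 20

    def test_rectangular_frames_of_constant_signal_identical(self):
        cfg = FrameConfig(window_function="rectangular")
        _, frames = frame_signal(np.full(SR // 2, 0.3), SR, cfg)
        assert np.allclose(frames, frames[0])

    def test_times_are_window_centers_spaced_by_hop(self):
        cfg = FrameConfig()
        times, _ = frame_signal(np.ones(SR), SR, cfg)
        assert times[0] == pytest.approx(0.025)
        assert np.diff(times) == pytest.approx(cfg.hop_samples(SR) / SR)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(np.ones(100), SR, FrameConfig())


class TestFrameRms:
    def test_constant_rectangular(self):
        assert frame_rms(np.full(128, 0.5)) == pytest.approx(0.5)

    def test_full_scale_sine_whole_periods(self):
        t = np.arange(SR // 10) / SR  # 100 ms = whole periods of 100 Hz
        assert frame_rms(np.sin(2 * np.pi * 100 * t)) == pytest.approx(
            1 / np.sqrt(2), rel=0.01)

    def test_zeros_and_empty(self):
        assert frame_rms(np.zeros(10)) == 0.0
        with pytest.raises(ValueError):
            frame_rms(np.array([]))


class TestTrajectory:
    def test_identical_channels_give_50(self, rng, default_filter, gate_off):
        x = rng.standard_normal(SR)
        traj = compute_trajectory(make_recording(x, x), default_filter,
                                  gate=gate_off)
        assert traj.valid_values == pytest.approx(50.0)

    def test_silent_nasal_gives_0(self, rng, default_filter, gate_off):
        x = rng.standard_normal(SR)
        traj = compute_trajectory(make_recording(np.zeros_like(x), x),
                                  default_filter, gate=gate_off)
        assert traj.valid_values == pytest.approx(0.0)

    def test_3_to_1_rms_ratio_gives_75(self, rng, default_filter, gate_off):
        x = rng.standard_normal(SR)
        traj = compute_trajectory(make_recording(3 * x, x), default_filter,
                                  gate=gate_off)
        assert traj.valid_values == pytest.approx(75.0)

    def test_gate_invalidates_exactly_injected_quiet_frames(self, rng):
        """Brute-force recount of frame RMS against the gate threshold."""
        sr = 8000
        cfg = FrameConfig()
        gate = GateConfig(floor_dbfs=-50.0)
        x = 0.3 * rng.standard_normal(4 * sr)
        # attenuate two disjoint spans far below the floor
        x[sr:sr + 1600] *= 1e-5
        x[3 * sr:3 * sr + 2400] *= 1e-5
        rec = make_recording(x, 0.5 * x, sample_rate=sr)
        traj = compute_trajectory(rec, passthrough(sr), cfg, gate)

        win, hop = cfg.window_samples(sr), cfg.hop_samples(sr)
        w = np.hanning(win)
        expected_invalid = 0
        for start in range(0, x.size - win + 1, hop):
            fn = rec.nasal[start:start + win] * w
            fo = rec.oral[start:start + win] * w
            combined = np.sqrt(np.mean(np.concatenate([fn, fo]) ** 2))
            if combined < 10 ** (-50 / 20):
                expected_invalid += 1
        assert expected_invalid > 0
        assert int(np.sum(~traj.valid)) == expected_invalid

    def test_zero_total_energy_frames_invalid_without_gate(self, gate_off):
        sr = 8000
        x = np.zeros(sr)
        x[: sr // 2] = 0.4
        traj = compute_trajectory(make_recording(x, x, sample_rate=sr),
                                  passthrough(sr), gate=gate_off)
        assert not np.all(traj.valid)
        assert np.all(np.isnan(traj.nasalance_pct[~np.asarray(traj.valid)]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 2**16))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        sr = 8000
        n = rng.standard_normal(sr // 2) * rng.uniform(0.1, 1)
        o = rng.standard_normal(sr // 2) * rng.uniform(0.1, 1)
        rec = make_recording(n, o, sample_rate=sr)
        scaled = make_recording(scale * n, scale * o, sample_rate=sr)
        gate = GateConfig(enabled=False)
        t1 = compute_trajectory(rec, passthrough(sr), gate=gate)
        t2 = compute_trajectory(scaled, passthrough(sr), gate=gate)
        assert np.allclose(t1.valid_values, t2.valid_values, atol=1e-8)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_channel_swap_antisymmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        sr = 8000
        rec = make_recording(rng.standard_normal(sr // 2),
                             rng.standard_normal(sr // 2), sample_rate=sr)
        gate = GateConfig(enabled=False)
        fwd = compute_trajectory(rec, passthrough(sr), gate=gate)
        rev = compute_trajectory(rec.swapped(), passthrough(sr), gate=gate)
        assert np.all(fwd.valid_values >= 0) and np.all(fwd.valid_values <= 100)
        assert np.allclose(fwd.valid_values, 100 - rev.valid_values, atol=1e-8)

    def test_csv_round_trip(self, rng, default_filter, tmp_path):
        x = rng.standard_normal(SR)
        traj = compute_trajectory(make_recording(x, 2 * x), default_filter)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = type(traj).from_csv(path)
        assert np.allclose(back.nasalance_pct, traj.nasalance_pct, equal_nan=True)
        assert back.hop_s == pytest.approx(traj.hop_s, rel=1e-6)


class TestSummary:
    def test_constant_trajectory(self, rng, default_filter, gate_off):
        x = rng.standard_normal(SR)
        traj = compute_trajectory(make_recording(x, x), default_filter,
                                  gate=gate_off)
        s = summarize(traj)
        assert s.mean_pct == pytest.approx(50.0)
        assert s.min_pct == s.max_pct == pytest.approx(50.0)
        assert s.sd_pct == pytest.approx(0.0, abs=1e-9)
        assert s.n_valid_frames == s.n_total_frames == traj.n_frames

    def test_matches_independent_recount(self, rng, default_filter):
        x = rng.standard_normal(2 * SR)
        y = rng.standard_normal(2 * SR) * (0.2 + np.abs(np.sin(
            2 * np.pi * 3 * np.arange(2 * SR) / SR)))
        traj = compute_trajectory(make_recording(x, y), default_filter)
        s = summarize(traj)
        vals = [p for p, v in zip(traj.nasalance_pct, traj.valid) if v]
        assert s.mean_pct == pytest.approx(np.mean(vals))
        assert s.min_pct == pytest.approx(min(vals))
        assert s.max_pct == pytest.approx(max(vals))
        assert s.sd_pct == pytest.approx(np.std(vals, ddof=1))
        assert s.n_valid_frames == len(vals)

    def test_unfiltered_mean_equals_trajectory_mean(self, rng, gate_off):
        # the property behind summary-vs-external cross-checks: the summary
        # mean is exactly the arithmetic mean of per-frame nasalance
        sr = 8000
        x = rng.standard_normal(sr)
        y = 0.5 * rng.standard_normal(sr)
        traj = compute_trajectory(make_recording(x, y, sample_rate=sr),
                                  passthrough(sr), gate=gate_off)
        assert summarize(traj).mean_pct == pytest.approx(
            float(np.mean(traj.valid_values)))

    def test_fully_gated_recording_rejected(self):
        sr = 8000
        quiet = np.full(sr, 1e-6)
        traj = compute_trajectory(make_recording(quiet, quiet, sample_rate=sr),
                                  passthrough(sr), gate=GateConfig())
        with pytest.raises(ValueError, match="valid"):
            summarize(traj)
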