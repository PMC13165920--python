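"""Synthetic dual-channel recordings with known nasalance ground truth.

Every downstream stage (filtering, framing, gating, nasalance,
isolation, agreement) can be exercised without any recorded speech: a
single source signal is split between the nasal and oral channels with
time-varying weights chosen so the ideal frame RMS ratio follows a
prescribed nasalance profile.  Cross-channel leakage (the finite
isolation of a real separator plate, expressed in dB) mixes a scaled
copy of each channel into the other, and an independent Gaussian noise
floor is added per channel.

Because both channels carry the same source waveform, the effect of
leakage on the measured nasalance has the closed form implemented in
:func:`expected_leakage_bias`, which serves as an analytic oracle: a
perfectly isolated device reads the profile exactly, while finite
isolation compresses readings toward 50% — oral-dominant material reads
high and nasal-dominant material reads low, the signature of a leaky
separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .audio_io import DualChannelRecording
from .filters import design_bandpass, apply_filter
from .nasalance import NasalanceTrajectory

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dual_recording",
    "apply_time_warp",
    "expected_leakage_bias",
    "parse_profile",
]

Profile = Callable[[np.ndarray], np.ndarray]


def _as_profile(profile) -> Profile:
    """Accept a constant, a piecewise-constant [(start_s, pct), ...] table,
    or a callable of time, and return a vectorized callable."""
    if callable(profile):
        return lambda t: np.asarray(profile(t), dtype=np.float64)
    if np.isscalar(profile):
        value = float(profile)
        return lambda t: np.full_like(np.asarray(t, dtype=float), value)
    knots = sorted((float(s), float(p)) for s, p in profile)
    starts = np.array([s for s, _ in knots])
    vals = np.array([p for _, p in knots])
    return lambda t: vals[np.clip(np.searchsorted(starts, t, side="right") - 1,
                                  0, len(vals) - 1)]


def parse_profile(text: str):
    """Parse a ``"start:pct,start:pct,..."`` profile string (CLI syntax)."""
    pairs = []
    for chunk in text.split(","):
        start, _, pct = chunk.partition(":")
        pairs.append((float(start), float(pct)))
    return pairs


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: what to synthesize and under which device model.

    ``isolation_db`` is the attenuation of the cross-channel leakage
    path (np.inf = perfectly isolated); ``noise_floor_dbfs`` the RMS of
    the per-channel additive Gaussian noise (-np.inf = noiseless).
    ``source_kind`` selects white noise, a 1 kHz-style sine, or
    "speech_like": 200-800 Hz band-limited noise amplitude-modulated at
    syllable rate (4 Hz), which exercises the analysis band with
    realistic dynamics.
    """

    duration_s: float = 5.0
    sample_rate: int = 44_100
    nasalance_profile: object = 50.0
    source_kind: str = "speech_like"
    isolation_db: float = np.inf
    noise_floor_dbfs: float = -np.inf
    sine_hz: float = 1000.0
    modulation_hz: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.isolation_db < 0:
            raise ValueError("isolation_db must be >= 0")
        if self.source_kind not in ("noise", "speech_like", "sine"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")

    @property
    def leakage_coefficient(self) -> float:
        return float(10.0 ** (-self.isolation_db / 20.0))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually built, for oracle comparisons."""

    times_s: np.ndarray
    profile_pct: np.ndarray
    leakage_coefficient: float
    noise_floor_dbfs: float
    warp_map: tuple[np.ndarray, np.ndarray] | None = None

    def expected_measured_pct(self) -> np.ndarray:
        """Profile after the closed-form leakage bias (noise ignored)."""
        iso_db = (np.inf if self.leakage_coefficient == 0
                  else -20.0 * np.log10(self.leakage_coefficient))
        return expected_leakage_bias(self.profile_pct, iso_db)


def _make_source(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    if cfg.source_kind == "sine":
        return np.sin(2 * np.pi * cfg.sine_hz * t)
    x = rng.standard_normal(n)
    if cfg.source_kind == "speech_like":
        spec = design_bandpass(200.0, 800.0, order=2, sample_rate=cfg.sample_rate)
        x = apply_filter(x, spec, mode="zero_phase")
        # syllable-rate envelope, kept strictly positive
        x *= 0.55 + 0.45 * np.sin(2 * np.pi * cfg.modulation_hz * t)
    x /= np.sqrt(np.mean(x ** 2))
    return x


def generate_dual_recording(cfg: SynthConfig) -> tuple[DualChannelRecording, GroundTruth]:
    """Synthesize a dual-channel recording realizing a nasalance profile.

    The common source s(t) is split as nasal = w_n(t) s, oral = w_o(t) s
    with w_n = p/100 and w_o = 1 - p/100, so the ideal frame RMS ratio
    equals the profile p(t).  Leakage then mixes alpha*oral into nasal
    and alpha*nasal into oral (alpha = 10^(-isolation_db/20)), and
    independent Gaussian noise at ``noise_floor_dbfs`` RMS is added per
    channel.  Deterministic for a fixed seed.  Peak amplitude is scaled
    to 0.5 full scale so the result is WAV-serializable without clipping.
    """
    rng = np.random.default_rng(cfg.seed)
    source = _make_source(cfg, rng)
    n = source.size
    t = np.arange(n) / cfg.sample_rate
    profile_fn = _as_profile(cfg.nasalance_profile)
    p = profile_fn(t)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("nasalance profile must stay within [0, 100]")
    w_nasal = p / 100.0
    w_oral = 1.0 - w_nasal
    alpha = cfg.leakage_coefficient

    nasal_clean = w_nasal * source
    oral_clean = w_oral * source
    nasal = nasal_clean + alpha * oral_clean
    oral = oral_clean + alpha * nasal_clean

    if np.isfinite(cfg.noise_floor_dbfs):
        noise_rms = 10.0 ** (cfg.noise_floor_dbfs / 20.0)
        nasal = nasal + noise_rms * rng.standard_normal(n)
        oral = oral + noise_rms * rng.standard_normal(n)

    peak = max(np.max(np.abs(nasal)), np.max(np.abs(oral)))
    if peak > 0:
        scale = 0.5 / peak
        nasal, oral = nasal * scale, oral * scale

    rec = DualChannelRecording(nasal=nasal, oral=oral, sample_rate=cfg.sample_rate)
    truth = GroundTruth(times_s=t, profile_pct=p,
                        leakage_coefficient=alpha,
                        noise_floor_dbfs=cfg.noise_floor_dbfs)
    return rec, truth


def expected_leakage_bias(profile_pct, isolation_db: float):
    """Nasalance actually measured when true ratio ``profile_pct`` leaks
    with isolation ``isolation_db``.

    With unit-total channel weights n = p/100, o = 1 - p/100 and leakage
    alpha, the measured ratio is (n + alpha*o) / ((n + alpha*o) +
    (o + alpha*n)) = (n + alpha*o) / (1 + alpha).  Scalar in, scalar
    out; arrays broadcast.
    """
    p = np.asarray(profile_pct, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("profile_pct must lie in [0, 100]")
    alpha = 10.0 ** (-float(isolation_db) / 20.0)
    n = p / 100.0
    out = 100.0 * (n + alpha * (1.0 - n)) / (1.0 + alpha)
    return float(out) if np.isscalar(profile_pct) else out


def apply_time_warp(obj, warp_map: tuple[Sequence[float], Sequence[float]]):
    """Resample a recording or trajectory along a monotone time warp.

    ``warp_map`` is ``(original_times, warped_times)`` knot arrays (both
    strictly increasing, same length, covering the input span); times
    between knots map linearly.  An event at original time t appears at
    warped time w(t), so a uniform 1.2x slowdown is
    ``([0, T], [0, 1.2*T])``.  Values are linearly interpolated onto the
    warped object's own uniform grid.

    Returns ``(warped_object, warp_map)``.
    """
    t_orig = np.asarray(warp_map[0], dtype=np.float64)
    t_new = np.asarray(warp_map[1], dtype=np.float64)
    if t_orig.shape != t_new.shape or t_orig.size < 2:
        raise ValueError("warp_map needs matching knot arrays of length >= 2")
    if np.any(np.diff(t_orig) <= 0) or np.any(np.diff(t_new) <= 0):
        raise ValueError("warp must be strictly increasing")

    def inverse(u: np.ndarray) -> np.ndarray:
        return np.interp(u, t_new, t_orig)

    if isinstance(obj, DualChannelRecording):
        sr = obj.sample_rate
        n_out = int(round(t_new[-1] * sr))
        u = np.arange(n_out) / sr
        src_t = inverse(u)
        grid = np.arange(obj.n_samples) / sr
        nasal = np.interp(src_t, grid, obj.nasal)
        oral = np.interp(src_t, grid, obj.oral)
        warped = DualChannelRecording(nasal=nasal, oral=oral, sample_rate=sr)
        return warped, (t_orig, t_new)

    if isinstance(obj, NasalanceTrajectory):
        hop = obj.hop_s
        t0 = obj.times_s[0]
        out_times = np.arange(t0, t_new[-1], hop)
        src_t = inverse(out_times)
        valid_t = obj.times_s[np.asarray(obj.valid, dtype=bool)]
        valid_v = obj.valid_values
        vals = np.interp(src_t, valid_t, valid_v)
        warped = NasalanceTrajectory(
            times_s=out_times, nasalance_pct=vals,
            valid=np.ones(out_times.size, dtype=bool),
            nasal_rms=np.zeros(out_times.size),
            oral_rms=np.zeros(out_times.size),
            hop_s=hop, config=dict(obj.config, warped=True),
        )
        return warped, (t_orig, t_new)

    raise TypeError(f"cannot warp object of type {type(obj).__name__}")
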