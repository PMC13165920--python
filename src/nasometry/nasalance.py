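"""Frame-based nasalance: framing, RMS, energy gating, trajectory, summary.

Nasalance is the percentage of nasal acoustic energy in the combined
nasal + oral signal,

    nasalance = N / (N + O) x 100%,

where N and O are the per-frame RMS amplitudes of the band-pass filtered
nasal and oral channels.  The RMS (amplitude) reading of "energy" is the
one operationalized here by default; squared-energy weighting is exposed
via ``energy_mode="squared"``.

Frames whose combined two-channel RMS falls below a sound-floor gate are
marked invalid and excluded from the trajectory values and the session
summary, which suppresses noise-dominated estimates during pauses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import DualChannelRecording
from .filters import FilterSpec, apply_filter

__all__ = [
    "FrameConfig",
    "GateConfig",
    "FrameEnergies",
    "NasalanceTrajectory",
    "NasalanceSummary",
    "frame_signal",
    "frame_rms",
    "compute_trajectory",
    "summarize",
]


@dataclass(frozen=True)
class FrameConfig:
    """Analysis framing: window length, overlap fraction, window shape.

    Defaults are 50-ms Hann windows with 50% overlap, the setting used
    for trajectory analysis; both are session parameters in the app.
    """

    window_s: float = 0.050
    overlap_fraction: float = 0.5
    window_function: str = "hann"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_function not in ("hann", "rectangular"):
            raise ValueError(f"unknown window function {self.window_function!r}")

    def window_samples(self, sample_rate: int) -> int:
        n = int(round(self.window_s * sample_rate))
        if n < 1:
            raise ValueError("window shorter than one sample at this rate")
        return n

    def hop_samples(self, sample_rate: int) -> int:
        hop = int(round(self.window_samples(sample_rate) * (1.0 - self.overlap_fraction)))
        return max(hop, 1)

    def window_array(self, n: int) -> np.ndarray:
        if self.window_function == "hann":
            return np.hanning(n)
        return np.ones(n)

    def config_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "overlap_fraction": self.overlap_fraction,
            "window_function": self.window_function,
        }


@dataclass(frozen=True)
class GateConfig:
    """Sound-floor energy gate on the combined two-channel frame RMS.

    ``floor_dbfs`` is a threshold in dB re digital full scale; frames
    whose combined RMS sits below it are invalid.  The default -50 dBFS
    sits well below conversational speech recorded at typical levels yet
    above a quiet noise floor.
    """

    floor_dbfs: float = -50.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.floor_dbfs > 0:
            raise ValueError("floor_dbfs must be <= 0 (dB re full scale)")

    @property
    def floor_linear(self) -> float:
        return 10.0 ** (self.floor_dbfs / 20.0)

    def config_dict(self) -> dict:
        return {"floor_dbfs": self.floor_dbfs, "enabled": self.enabled}


@dataclass(frozen=True)
class FrameEnergies:
    """Per-frame RMS amplitudes of both filtered channels."""

    time_s: np.ndarray
    nasal_rms: np.ndarray
    oral_rms: np.ndarray
    combined_rms: np.ndarray


@dataclass(frozen=True)
class NasalanceTrajectory:
    """Per-frame nasalance with validity mask and full provenance.

    Invalid frames carry NaN in ``nasalance_pct``; valid values lie in
    [0, 100].  ``config`` echoes the framing, gating and filter settings
    that produced the trajectory.
    """

    times_s: np.ndarray
    nasalance_pct: np.ndarray
    valid: np.ndarray
    nasal_rms: np.ndarray
    oral_rms: np.ndarray
    hop_s: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("nasalance_pct", "valid", "nasal_rms", "oral_rms"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory field lengths differ")
        vals = np.asarray(self.nasalance_pct)[np.asarray(self.valid, dtype=bool)]
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 100 + 1e-9):
            raise ValueError("valid nasalance values must lie in [0, 100]")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def valid_values(self) -> np.ndarray:
        return np.asarray(self.nasalance_pct)[np.asarray(self.valid, dtype=bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times_s,
            "nasalance_pct": self.nasalance_pct,
            "valid": np.asarray(self.valid, dtype=bool),
            "nasal_rms": self.nasal_rms,
            "oral_rms": self.oral_rms,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NasalanceTrajectory":
        df = pd.read_csv(path)
        times = df["time_s"].to_numpy(dtype=float)
        hop = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
        return cls(
            times_s=times,
            nasalance_pct=df["nasalance_pct"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=bool),
            nasal_rms=df.get("nasal_rms", pd.Series(np.zeros(len(df)))).to_numpy(dtype=float),
            oral_rms=df.get("oral_rms", pd.Series(np.zeros(len(df)))).to_numpy(dtype=float),
            hop_s=hop,
        )


@dataclass(frozen=True)
class NasalanceSummary:
    """Session statistics over valid frames (mean, min, max, sample SD)."""

    mean_pct: float
    min_pct: float
    max_pct: float
    sd_pct: float
    n_valid_frames: int
    n_total_frames: int

    def to_dict(self) -> dict:
        return {
            "mean_pct": self.mean_pct,
            "min_pct": self.min_pct,
            "max_pct": self.max_pct,
            "sd_pct": self.sd_pct,
            "n_valid_frames": self.n_valid_frames,
            "n_total_frames": self.n_total_frames,
        }


def frame_signal(x: np.ndarray, sample_rate: int,
                 cfg: FrameConfig) -> tuple[np.ndarray, np.ndarray]:
    """Slice a signal into overlapping windowed frames.

    Returns ``(times_s, frames)`` where ``times_s`` are window-center
    times and ``frames`` has shape (n_frames, window_samples) with the
    window function already applied.  Frames start at multiples of the
    hop; a trailing partial window is discarded.
    """
    x = np.asarray(x, dtype=np.float64)
    win = cfg.window_samples(sample_rate)
    hop = cfg.hop_samples(sample_rate)
    if x.size < win:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {win}-sample window"
        )
    n_frames = (x.size - win) // hop + 1
    starts = np.arange(n_frames) * hop
    idx = starts[:, None] + np.arange(win)[None, :]
    frames = x[idx] * cfg.window_array(win)[None, :]
    times = (starts + win / 2.0) / sample_rate
    return times, frames


def frame_rms(frame: np.ndarray) -> float:
    """Root-mean-square amplitude of one (windowed) frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.sqrt(np.mean(frame ** 2)))


def _rows_rms(frames: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(frames ** 2, axis=1))


def compute_trajectory(rec: DualChannelRecording, filt: FilterSpec,
                       fcfg: FrameConfig | None = None,
                       gate: GateConfig | None = None,
                       filter_mode: str = "causal",
                       energy_mode: str = "rms") -> NasalanceTrajectory:
    """Compute the per-frame nasalance trajectory of a dual-channel recording.

    Both channels are filtered identically over the whole signal, then
    framed on the same grid.  Per frame,

        nasalance_pct = 100 * N / (N + O)

    with N, O the windowed RMS amplitudes (or squared energies when
    ``energy_mode="squared"``).  A frame is invalid when the gate is
    enabled and the combined RMS over both channels' windowed samples
    jointly falls below the floor, or when N + O == 0.
    """
    if fcfg is None:
        fcfg = FrameConfig()
    if gate is None:
        gate = GateConfig()
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if energy_mode not in ("rms", "squared"):
        raise ValueError(f"energy_mode must be 'rms' or 'squared', got {energy_mode!r}")

    nasal_f = apply_filter(rec.nasal, filt, mode=filter_mode)
    oral_f = apply_filter(rec.oral, filt, mode=filter_mode)
    times, nasal_frames = frame_signal(nasal_f, rec.sample_rate, fcfg)
    _, oral_frames = frame_signal(oral_f, rec.sample_rate, fcfg)

    nasal_rms = _rows_rms(nasal_frames)
    oral_rms = _rows_rms(oral_frames)
    # RMS over both channels' samples pooled into one 2W-sample frame
    combined_rms = np.sqrt((nasal_rms ** 2 + oral_rms ** 2) / 2.0)

    if energy_mode == "rms":
        num, den = nasal_rms, nasal_rms + oral_rms
    else:
        num, den = nasal_rms ** 2, nasal_rms ** 2 + oral_rms ** 2

    valid = den > 0
    if gate.enabled:
        valid &= combined_rms >= gate.floor_linear

    pct = np.full(times.shape, np.nan)
    np.divide(num, den, out=pct, where=valid)
    pct[valid] *= 100.0

    hop_s = fcfg.hop_samples(rec.sample_rate) / rec.sample_rate
    config = {
        "frame": fcfg.config_dict(),
        "gate": gate.config_dict(),
        "filter": filt.config_dict(),
        "filter_mode": filter_mode,
        "energy_mode": energy_mode,
        "sample_rate": rec.sample_rate,
    }
    return NasalanceTrajectory(times_s=times, nasalance_pct=pct, valid=valid,
                               nasal_rms=nasal_rms, oral_rms=oral_rms,
                               hop_s=hop_s, config=config)


def summarize(traj: NasalanceTrajectory) -> NasalanceSummary:
    """Session-level mean/min/max/SD over valid frames (SD uses n-1)."""
    vals = traj.valid_values
    if vals.size == 0:
        raise ValueError("no valid frames: recording fully gated or silent")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return NasalanceSummary(
        mean_pct=float(np.mean(vals)),
        min_pct=float(np.min(vals)),
        max_pct=float(np.max(vals)),
        sd_pct=sd,
        n_valid_frames=int(vals.size),
        n_total_frames=int(traj.n_frames),
    )
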