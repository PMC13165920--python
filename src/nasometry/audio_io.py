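"""Stereo audio I/O with nasal/oral channel semantics.

Two container formats are supported: RIFF PCM WAV (what the commercial
NM 6500 software records, typically at 11,025 Hz) and headerless raw PCM
(what the mobile app writes to internal storage: 16-bit signed
little-endian interleaved stereo, 44,100 Hz unless stated otherwise).
Samples are held as normalized floats in [-1, 1]; the integer full scale
is 32768, so -1.0 is exactly representable and +1.0 clips to 32767.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Channel",
    "ChannelMap",
    "StereoRecording",
    "DualChannelRecording",
    "read_wav",
    "write_wav",
    "read_raw_pcm",
    "write_raw_pcm",
    "assign_channels",
]

#: Divisor mapping 16-bit integer samples onto [-1, 1].
FULL_SCALE_16 = 32768.0

DEFAULT_PCM_RATE = 44_100
DEFAULT_BIT_DEPTH = 16


class Channel(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class ChannelMap:
    """Which physical channel carries the nasal vs. oral microphone."""

    nasal: Channel = Channel.LEFT

    def __post_init__(self) -> None:
        object.__setattr__(self, "nasal", Channel(self.nasal))

    @property
    def oral(self) -> Channel:
        return Channel.RIGHT if self.nasal is Channel.LEFT else Channel.LEFT

    def swapped(self) -> "ChannelMap":
        return ChannelMap(nasal=self.oral)


@dataclass(frozen=True)
class StereoRecording:
    """Two equal-length channels of normalized samples at a common rate."""

    samples_left: np.ndarray
    samples_right: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        left = np.asarray(self.samples_left, dtype=np.float64)
        right = np.asarray(self.samples_right, dtype=np.float64)
        if left.ndim != 1 or right.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if left.shape != right.shape:
            raise ValueError(
                f"channel length mismatch: {left.size} vs {right.size}"
            )
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise ValueError("samples must be finite")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate}")
        object.__setattr__(self, "samples_left", left)
        object.__setattr__(self, "samples_right", right)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return self.samples_left.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class DualChannelRecording:
    """Stereo recording with channel roles resolved to nasal and oral."""

    nasal: np.ndarray
    oral: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        nasal = np.asarray(self.nasal, dtype=np.float64)
        oral = np.asarray(self.oral, dtype=np.float64)
        if nasal.shape != oral.shape or nasal.ndim != 1:
            raise ValueError("nasal and oral channels must be 1-D and equal length")
        if not (np.all(np.isfinite(nasal)) and np.all(np.isfinite(oral))):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "nasal", nasal)
        object.__setattr__(self, "oral", oral)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return self.nasal.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def swapped(self) -> "DualChannelRecording":
        return DualChannelRecording(nasal=self.oral, oral=self.nasal,
                                    sample_rate=self.sample_rate)


def read_wav(path: str | Path) -> StereoRecording:
    """Read a 2-channel PCM WAV into a normalized :class:`StereoRecording`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file is mono, has more than two channels, or uses an
        unsupported (non-integer-PCM) encoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 2 or data.shape[1] != 2:
        n_ch = 1 if data.ndim == 1 else data.shape[1]
        raise ValueError(f"expected a 2-channel WAV, got {n_ch} channel(s): {path}")
    if data.dtype == np.int16:
        scaled = data.astype(np.float64) / FULL_SCALE_16
    elif data.dtype == np.int32:
        scaled = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        scaled = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        scaled = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}: {path}")
    return StereoRecording(scaled[:, 0], scaled[:, 1], int(rate))


def write_wav(rec: StereoRecording, path: str | Path,
              bit_depth: int = DEFAULT_BIT_DEPTH) -> None:
    """Write a stereo recording as integer-PCM WAV.

    Amplitudes outside [-1, 1] are clamped with a warning; ``read_wav``
    inverts the result exactly at matching depth.
    """
    if bit_depth != 16:
        raise ValueError(f"only 16-bit WAV output is supported, got {bit_depth}")
    stacked = np.column_stack([rec.samples_left, rec.samples_right])
    if np.any(np.abs(stacked) > 1.0):
        warnings.warn("amplitudes outside [-1, 1] clamped on WAV write", stacklevel=2)
        stacked = np.clip(stacked, -1.0, 1.0)
    ints = _quantize16(stacked)
    wavfile.write(str(path), rec.sample_rate, ints)


def _quantize16(x: np.ndarray) -> np.ndarray:
    # round-half-away quantization; +1.0 saturates at 32767
    q = np.floor(x * FULL_SCALE_16 + 0.5)
    return np.clip(q, -32768, 32767).astype(np.int16)


def read_raw_pcm(path: str | Path, sample_rate: int = DEFAULT_PCM_RATE,
                 bit_depth: int = DEFAULT_BIT_DEPTH) -> StereoRecording:
    """Decode headerless interleaved stereo PCM.

    The dialect is fixed as 16-bit signed little-endian, left channel
    first within each frame; the byte stream carries no rate, so the
    caller supplies it (default 44,100 Hz).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if bit_depth != 16:
        raise ValueError(f"unsupported raw PCM bit depth {bit_depth}")
    raw = path.read_bytes()
    frame_bytes = 2 * (bit_depth // 8)
    if len(raw) == 0 or len(raw) % frame_bytes != 0:
        raise ValueError(
            f"{path}: {len(raw)} bytes is not a whole number of "
            f"{frame_bytes}-byte stereo frames"
        )
    ints = np.frombuffer(raw, dtype="<i2").reshape(-1, 2)
    scaled = ints.astype(np.float64) / FULL_SCALE_16
    return StereoRecording(scaled[:, 0], scaled[:, 1], sample_rate)


def write_raw_pcm(rec: StereoRecording, path: str | Path,
                  bit_depth: int = DEFAULT_BIT_DEPTH) -> None:
    """Serialize a stereo recording in the raw PCM dialect of ``read_raw_pcm``."""
    if bit_depth != 16:
        raise ValueError(f"unsupported raw PCM bit depth {bit_depth}")
    stacked = np.column_stack([rec.samples_left, rec.samples_right])
    if np.any(np.abs(stacked) > 1.0):
        warnings.warn("amplitudes outside [-1, 1] clamped on PCM write", stacklevel=2)
        stacked = np.clip(stacked, -1.0, 1.0)
    ints = _quantize16(stacked).astype("<i2")
    Path(path).write_bytes(ints.tobytes())


def assign_channels(rec: StereoRecording,
                    channel_map: ChannelMap | None = None) -> DualChannelRecording:
    """Resolve left/right into nasal/oral roles without touching sample values."""
    if channel_map is None:
        channel_map = ChannelMap()
    nasal = rec.samples_left if channel_map.nasal is Channel.LEFT else rec.samples_right
    oral = rec.samples_right if channel_map.nasal is Channel.LEFT else rec.samples_left
    return DualChannelRecording(nasal=nasal, oral=oral, sample_rate=rec.sample_rate)
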