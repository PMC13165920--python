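"""Electroacoustic device-evaluation analyses.

Covers the measurements used to characterize a nasometer headset on the
bench: long-term average spectra (LTAS) aggregated into 50-Hz bands,
mean absolute difference (MAD) between LTAS curves, the oral-nasal
intensity gap that quantifies channel isolation, and total harmonic
distortion (THD) of a sine response.

Levels are in dB re digital full scale; because the digital reference is
arbitrary, differences (MAD, gaps, relative curves) are the primary
comparable quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from .audio_io import DualChannelRecording
from .filters import FilterSpec, apply_filter

__all__ = [
    "LTASCurve",
    "IsolationResult",
    "compute_ltas",
    "normalize_relative",
    "ltas_mad",
    "intensity_gap",
    "compute_thd",
]


@dataclass(frozen=True)
class LTASCurve:
    """Long-term average spectrum aggregated into fixed-width bands.

    Bands tile ``range_hz`` as half-open intervals [low, low + width);
    centers sit at low + width/2.  ``mode`` is "absolute" (dB re full
    scale) or "relative" (each curve normalized to its own maximum, so
    max(levels) == 0 dB).
    """

    band_centers_hz: np.ndarray
    levels_db: np.ndarray
    mode: str
    range_hz: tuple[float, float]
    band_width_hz: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers_hz, dtype=np.float64)
        levels = np.asarray(self.levels_db, dtype=np.float64)
        if centers.shape != levels.shape:
            raise ValueError("band centers and levels must have equal length")
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"mode must be absolute/relative, got {self.mode!r}")
        object.__setattr__(self, "band_centers_hz", centers)
        object.__setattr__(self, "levels_db", levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band_center_hz": self.band_centers_hz,
            "level_db": self.levels_db,
            "mode": self.mode,
        })


@dataclass(frozen=True)
class IsolationResult:
    """Whole-recording channel levels and their difference (oral - nasal).

    With a single oral-side source, the gap measures how much quieter the
    leaked signal is in the nasal channel: higher gap = better isolation.
    """

    oral_level_db: float
    nasal_level_db: float

    @property
    def gap_db(self) -> float:
        return self.oral_level_db - self.nasal_level_db


def compute_ltas(x: np.ndarray, sample_rate: int,
                 band_width_hz: float = 50.0,
                 range_hz: tuple[float, float] = (100.0, 1000.0),
                 segment_s: float = 1.0) -> LTASCurve:
    """LTAS by overlapped averaged periodograms, power-summed into bands.

    The power spectral density is estimated over the entire signal with
    Hann-windowed segments (default 1 s) at 50% overlap, then PSD power
    is integrated within each ``band_width_hz``-wide band across
    ``range_hz`` and converted to dB.
    """
    x = np.asarray(x, dtype=np.float64)
    lo, hi = range_hz
    if hi > sample_rate / 2:
        raise ValueError(f"range {range_hz} exceeds Nyquist {sample_rate / 2}")
    if not np.isclose((hi - lo) / band_width_hz, round((hi - lo) / band_width_hz)):
        raise ValueError(f"band width {band_width_hz} does not tile range {range_hz}")
    nperseg = int(round(segment_s * sample_rate))
    if x.size < nperseg:
        raise ValueError(f"signal shorter than one {segment_s}-s analysis segment")
    freqs, psd = sig.welch(x, fs=sample_rate, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend=False)
    df = freqs[1] - freqs[0]
    n_bands = int(round((hi - lo) / band_width_hz))
    lows = lo + band_width_hz * np.arange(n_bands)
    levels = np.empty(n_bands)
    for i, band_lo in enumerate(lows):
        in_band = (freqs >= band_lo) & (freqs < band_lo + band_width_hz)
        power = np.sum(psd[in_band]) * df
        levels[i] = 10.0 * np.log10(power) if power > 0 else -np.inf
    return LTASCurve(band_centers_hz=lows + band_width_hz / 2.0,
                     levels_db=levels, mode="absolute",
                     range_hz=(lo, hi), band_width_hz=band_width_hz)


def normalize_relative(curve: LTASCurve) -> LTASCurve:
    """Shift a curve so its maximum sits at 0 dB (spectral-shape view)."""
    if curve.mode != "absolute":
        raise ValueError("normalize_relative expects an absolute-mode curve")
    peak = np.max(curve.levels_db)
    if not np.isfinite(peak):
        raise ValueError("cannot normalize an all-silent curve")
    return LTASCurve(band_centers_hz=curve.band_centers_hz,
                     levels_db=curve.levels_db - peak, mode="relative",
                     range_hz=curve.range_hz, band_width_hz=curve.band_width_hz)


def ltas_mad(a: LTASCurve, b: LTASCurve,
             band_hz: tuple[float, float] = (200.0, 800.0)) -> float:
    """Mean absolute difference (dB) between two curves over a band.

    Bands whose centers fall inside ``band_hz`` (inclusive) contribute;
    the curves must share the band grid and mode.
    """
    if a.band_centers_hz.shape != b.band_centers_hz.shape or \
            not np.allclose(a.band_centers_hz, b.band_centers_hz):
        raise ValueError("mismatched LTAS band grids")
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode} vs {b.mode}")
    lo, hi = band_hz
    sel = (a.band_centers_hz >= lo) & (a.band_centers_hz <= hi)
    if not np.any(sel):
        raise ValueError(f"no bands inside {band_hz}")
    return float(np.mean(np.abs(a.levels_db[sel] - b.levels_db[sel])))


def intensity_gap(rec: DualChannelRecording,
                  filt: FilterSpec | None = None,
                  filter_mode: str = "causal") -> IsolationResult:
    """Oral-minus-nasal level difference over the whole recording.

    Each channel level is 20*log10 of its whole-recording RMS after
    optional band-pass filtering.  Antisymmetric under channel swap.
    """
    nasal = rec.nasal if filt is None else apply_filter(rec.nasal, filt, filter_mode)
    oral = rec.oral if filt is None else apply_filter(rec.oral, filt, filter_mode)
    nasal_rms = np.sqrt(np.mean(nasal ** 2))
    oral_rms = np.sqrt(np.mean(oral ** 2))
    if nasal_rms == 0 or oral_rms == 0:
        raise ValueError("silent channel: intensity gap undefined")
    return IsolationResult(oral_level_db=float(20 * np.log10(oral_rms)),
                           nasal_level_db=float(20 * np.log10(nasal_rms)))


def compute_thd(x: np.ndarray, sample_rate: int, fundamental_hz: float = 1000.0,
                n_harmonics: int = 5) -> float:
    """Total harmonic distortion of a steady tone, in percent.

    THD% = 100 * sqrt(sum of harmonic powers 2..n) / sqrt(fundamental
    power).  Each component's power is integrated from a Hann-windowed
    spectrum around the spectral peak found within a small search window
    at the nominal harmonic frequency; integrating the whole main lobe
    makes the power ratio insensitive to spectral leakage.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < sample_rate // 10:
        raise ValueError("signal too short for THD estimation")
    win = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * win)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    bin_hz = freqs[1]

    def component_power(f_target: float) -> float:
        search = max(2, int(round(0.02 * f_target / bin_hz)))
        k0 = int(round(f_target / bin_hz))
        lo, hi = max(k0 - search, 0), min(k0 + search + 1, spec.size)
        if lo >= hi:
            return 0.0
        peak = lo + int(np.argmax(spec[lo:hi]))
        a, b = max(peak - 3, 0), min(peak + 4, spec.size)
        return float(np.sum(spec[a:b]))

    p1 = component_power(fundamental_hz)
    if p1 <= 0 or p1 < 1e-12 * np.max(spec):
        raise ValueError(f"no detectable fundamental near {fundamental_hz} Hz")
    p_harm = 0.0
    for k in range(2, n_harmonics + 1):
        fk = k * fundamental_hz
        if fk >= sample_rate / 2:
            break
        p_harm += component_power(fk)
    return 100.0 * float(np.sqrt(p_harm / p1))
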