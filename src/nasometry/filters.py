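"""Butterworth bandpass filtering applied ahead of all energy estimation.

The measurement pipeline band-limits both channels to the nasalance-
relevant range (default 200-800 Hz) with a 2nd-order Butterworth IIR
bandpass before frame RMS is computed.  ``order`` follows the scipy /
MATLAB ``butter`` convention: it is the order of the lowpass prototype,
so an order-2 bandpass has four poles.  Either reading of "2nd order"
places the -3 dB points at both cutoffs; the prototype reading
additionally gives the expected >20 dB stopband attenuation one octave
outside the band, and a single-biquad variant remains available via
``order=1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "design_bandpass", "passthrough", "apply_filter",
           "frequency_response_db"]


@dataclass(frozen=True)
class FilterSpec:
    """Designed rational transfer function plus its design parameters.

    ``low_hz``/``high_hz`` are the -3 dB edges, ``order`` the Butterworth
    design (prototype) order.  A spec with ``b=[1], a=[1]`` is a pass-through used
    for recordings analyzed as provided (no additional filtering).
    """

    low_hz: float | None
    high_hz: float | None
    order: int
    sample_rate: int
    b: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        a = np.atleast_1d(np.asarray(self.a, dtype=np.float64))
        if a[0] != 1.0:
            b = b / a[0]
            a = a / a[0]
        # stability: poles strictly inside the unit circle
        if a.size > 1 and np.any(np.abs(np.roots(a)) >= 1.0):
            raise ValueError("unstable filter: poles on or outside the unit circle")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", a)

    @property
    def is_passthrough(self) -> bool:
        return self.b.size == 1 and self.a.size == 1 and self.b[0] == 1.0

    def config_dict(self) -> dict:
        return {
            "low_hz": self.low_hz,
            "high_hz": self.high_hz,
            "order": self.order,
            "sample_rate": self.sample_rate,
            "passthrough": self.is_passthrough,
        }


def design_bandpass(low_hz: float, high_hz: float, order: int = 2,
                    sample_rate: int = 44_100) -> FilterSpec:
    """Design a Butterworth bandpass with -3 dB points at ``low_hz``/``high_hz``.

    ``order`` is the design order in the ``butter`` convention (lowpass
    prototype order; the bandpass transfer function has ``2 * order``
    poles).
    """
    nyquist = sample_rate / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    b, a = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=sample_rate)
    return FilterSpec(low_hz=low_hz, high_hz=high_hz, order=order,
                      sample_rate=sample_rate, b=b, a=a)


def passthrough(sample_rate: int) -> FilterSpec:
    """Identity filter spec, for recordings analyzed without band-limiting."""
    return FilterSpec(low_hz=None, high_hz=None, order=0,
                      sample_rate=sample_rate, b=np.ones(1), a=np.ones(1))


def apply_filter(x: np.ndarray, spec: FilterSpec,
                 mode: str = "causal") -> np.ndarray:
    """Filter a signal sampled at ``spec.sample_rate``.

    ``causal`` is a single forward pass, matching the streaming app;
    ``zero_phase`` runs forward-backward (squared magnitude response,
    no group delay) for offline spectral work.  Output length equals
    input length in both modes.
    """
    x = np.asarray(x, dtype=np.float64)
    if spec.is_passthrough:
        return x.copy()
    if mode == "causal":
        return signal.lfilter(spec.b, spec.a, x)
    if mode == "zero_phase":
        return signal.filtfilt(spec.b, spec.a, x)
    raise ValueError(f"mode must be 'causal' or 'zero_phase', got {mode!r}")


def frequency_response_db(spec: FilterSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response in dB at the given frequencies."""
    freqs_hz = np.asarray(freqs_hz, dtype=np.float64)
    _, h = signal.freqz(spec.b, spec.a, worN=2 * np.pi * freqs_hz / spec.sample_rate)
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(np.abs(h))
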