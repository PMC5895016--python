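"""Temporal bandpass filtering of per-pixel, per-band time series.

The magnification pipelines isolate the motion frequencies of interest
(0.2-0.3 Hz for adult breathing) with a digital Butterworth bandpass —
maximally flat in the passband, monotonic overall — applied forward and
backward (zero phase).  Zero-phase application matters here: a one-way IIR
pass would delay the motion signal and shift the synthesized motion in
time.  The filter order defaults to 1; the effective order is doubled by
the two passes.

An ideal (FFT brick-wall) bandpass is provided as an independent
cross-check, not as the default path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DimensionError

__all__ = [
    "BandpassSpec",
    "design_bandpass",
    "frequency_response",
    "apply_bandpass",
    "apply_bandpass_stack",
    "apply_ideal_bandpass",
]


@dataclass
class BandpassSpec:
    """Realized temporal bandpass filter.

    ``sos`` holds the second-order sections of the digital Butterworth
    design; ``f_l``/``f_h`` are the passband edges in Hz and ``fs`` the
    sampling rate.
    """

    f_l: float
    f_h: float
    fs: float
    order: int = 1
    kind: str = "butterworth"
    sos: np.ndarray = field(default=None, repr=False)

    @property
    def center(self) -> float:
        """Geometric centre frequency of the passband (Hz)."""
        return float(np.sqrt(self.f_l * self.f_h))

    def min_length(self) -> int:
        """Smallest series length the zero-phase application accepts."""
        return max(3 * self.order, self.padlen() + 1)

    def padlen(self) -> int:
        ntaps = 2 * self.sos.shape[0] + 1
        return 3 * ntaps


def design_bandpass(f_l: float, f_h: float, fs: float, order: int = 1) -> BandpassSpec:
    """Digital Butterworth bandpass with edges ``(f_l, f_h)`` Hz at ``fs`` Hz."""
    if not f_l > 0:
        raise ConfigurationError(f"f_l must be > 0; got {f_l}")
    if not f_l < f_h:
        raise ConfigurationError(f"need f_l < f_h; got ({f_l}, {f_h})")
    if not f_h < fs / 2.0:
        raise ConfigurationError(
            f"f_h={f_h} Hz is not below the Nyquist frequency {fs / 2.0} Hz"
        )
    if order < 1:
        raise ConfigurationError(f"order must be >= 1; got {order}")
    sos = signal.butter(order, [f_l, f_h], btype="bandpass", fs=fs, output="sos")
    return BandpassSpec(f_l=f_l, f_h=f_h, fs=fs, order=order, sos=sos)


def frequency_response(spec: BandpassSpec, freqs) -> np.ndarray:
    """Single-pass magnitude response of the realized filter at ``freqs`` Hz."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    _, h = signal.sosfreqz(spec.sos, worN=2.0 * np.pi * freqs / spec.fs)
    return np.abs(h)


def _check_length(n: int, spec: BandpassSpec) -> None:
    if n < spec.min_length():
        raise DimensionError(
            f"series of length {n} is too short for zero-phase filtering "
            f"(need >= {spec.min_length()} samples)"
        )


def apply_bandpass(series: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase (forward-backward) bandpass of a 1-D time series."""
    series = np.asarray(series, dtype=np.float64)
    _check_length(series.shape[-1], spec)
    return signal.sosfiltfilt(spec.sos, series, padtype="odd", padlen=spec.padlen())


def apply_bandpass_stack(
    stack: np.ndarray, spec: BandpassSpec, axis: int = 0
) -> np.ndarray:
    """Apply the same filter independently along ``axis`` at every position.

    Complex inputs are reduced to their real part before filtering (phase
    deltas are real-valued by construction).
    """
    stack = np.asarray(stack)
    if np.iscomplexobj(stack):
        stack = np.real(stack)
    stack = stack.astype(np.float64, copy=False)
    _check_length(stack.shape[axis], spec)
    return signal.sosfiltfilt(
        spec.sos, stack, axis=axis, padtype="odd", padlen=spec.padlen()
    )


def apply_ideal_bandpass(
    stack: np.ndarray, spec: BandpassSpec, axis: int = 0
) -> np.ndarray:
    """Brick-wall FFT bandpass retaining frequencies in ``[f_l, f_h]``.

    Cross-check oracle for the Butterworth path; assumes the series is long
    enough that spectral leakage is negligible.
    """
    stack = np.asarray(stack)
    if np.iscomplexobj(stack):
        stack = np.real(stack)
    stack = stack.astype(np.float64, copy=False)
    n = stack.shape[axis]
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / spec.fs))
    mask = (freqs >= spec.f_l) & (freqs <= spec.f_h)
    spectrum = np.fft.fft(stack, axis=axis)
    shape = [1] * stack.ndim
    shape[axis] = n
    spectrum *= mask.reshape(shape)
    return np.real(np.fft.ifft(spectrum, axis=axis))
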