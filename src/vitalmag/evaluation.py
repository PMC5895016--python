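"""Quality metrics, pixel traces, displacement measurement and breath-rate
estimation.

MSE/PSNR follow the video-coding convention on the 0-255 intensity scale:
``PSNR = 10 log10(255^2 / MSE)`` with the MSE of an RGB video taken as the
arithmetic mean of the per-channel MSEs, averaged over frames.  PSNR has no
absolute meaning here; it only ranks the degradation different
magnification settings introduce relative to the original video.

``measure_displacement`` recovers the per-frame sub-pixel translation of a
region via upsampled phase cross-correlation against frame 0.  It is the
toolkit's independent motion oracle: amplification factors are verified by
comparing measured output motion against the generator's ground truth,
never by trusting the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sp_signal
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, DimensionError
from .video_io import VideoTensor

__all__ = [
    "QualityReport",
    "MotionTrace",
    "BreathRateResult",
    "mse",
    "psnr",
    "quality_report",
    "pixel_trace",
    "measure_displacement",
    "fit_sinusoid_amplitude",
    "estimate_breath_rate",
]


@dataclass
class QualityReport:
    """MSE/PSNR summary of a magnified video against its original."""

    mse: float
    psnr: float
    per_channel_mse: Tuple[float, ...]
    frame_psnr: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr_db": self.psnr,
            "per_channel_mse": list(self.per_channel_mse),
            "frame_psnr_db": [float(v) for v in self.frame_psnr],
        }


@dataclass
class MotionTrace:
    """A per-frame scalar series: pixel intensity (0-255) or displacement (px)."""

    values: np.ndarray
    fps: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


def _check_same_shape(original: VideoTensor, magnified: VideoTensor) -> None:
    if original.shape != magnified.shape:
        raise DimensionError(
            f"video shapes differ: {original.shape} vs {magnified.shape}"
        )


def _frame_channel_mse(original: VideoTensor, magnified: VideoTensor) -> np.ndarray:
    """(T, C) matrix of per-frame, per-channel MSEs on the 0-255 scale."""
    diff = 255.0 * (original.frames - magnified.frames)
    return np.mean(diff**2, axis=(1, 2))


def mse(original: VideoTensor, magnified: VideoTensor) -> float:
    """Mean squared error on the 0-255 scale, channels then frames averaged."""
    _check_same_shape(original, magnified)
    return float(np.mean(_frame_channel_mse(original, magnified)))


def _psnr_from_mse(value: float) -> float:
    if value <= 0.0:
        return float("inf")  # identical videos
    return float(10.0 * np.log10(255.0**2 / value))


def psnr(original: VideoTensor, magnified: VideoTensor) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical videos."""
    return _psnr_from_mse(mse(original, magnified))


def quality_report(original: VideoTensor, magnified: VideoTensor) -> QualityReport:
    _check_same_shape(original, magnified)
    fc = _frame_channel_mse(original, magnified)
    per_channel = tuple(float(v) for v in fc.mean(axis=0))
    overall = float(np.mean(per_channel))
    frame_psnr = np.array([_psnr_from_mse(float(v)) for v in fc.mean(axis=1)])
    return QualityReport(
        mse=overall,
        psnr=_psnr_from_mse(overall),
        per_channel_mse=per_channel,
        frame_psnr=frame_psnr,
    )


_CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2, "gray": 0}


def pixel_trace(video: VideoTensor, x: int, y: int, channel: str = "r") -> MotionTrace:
    """Per-frame intensity of one pixel on the 0-255 scale."""
    if channel not in _CHANNEL_INDEX:
        raise DimensionError(f"unknown channel {channel!r}")
    c = _CHANNEL_INDEX[channel]
    if not (0 <= x < video.width and 0 <= y < video.height and c < video.n_channels):
        raise IndexError(
            f"pixel ({x}, {y}, {channel}) out of bounds for video of shape {video.shape}"
        )
    return MotionTrace(
        values=255.0 * video.frames[:, y, x, c],
        fps=video.fps,
        source=f"pixel x={x} y={y} channel={channel}",
    )


def measure_displacement(
    video: VideoTensor,
    roi: Optional[Tuple[int, int, int, int]] = None,
    axis: str = "x",
    upsample_factor: int = 100,
) -> MotionTrace:
    """Sub-pixel translation of a region versus frame 0, per frame.

    ``roi`` is ``(x0, x1, y0, y1)`` in px (half-open); ``None`` uses the
    whole frame.  Displacement is estimated by phase cross-correlation with
    ``upsample_factor``-fold Fourier upsampling and reported along the
    requested axis, positive toward increasing coordinate.
    """
    frames = video.frames.mean(axis=-1)  # luma-agnostic: average channels
    if roi is not None:
        x0, x1, y0, y1 = roi
        frames = frames[:, y0:y1, x0:x1]
    if frames.shape[1] < 4 or frames.shape[2] < 4:
        raise DimensionError(f"ROI of shape {frames.shape[1:]} is too small")
    ref = frames[0]
    if np.var(ref) <= 1e-16:
        raise DegenerateInputError("ROI is textureless; displacement is undefined")
    axis_index = {"x": 1, "y": 0}[axis]
    values = np.empty(video.n_frames)
    values[0] = 0.0
    for i in range(1, video.n_frames):
        shift, _, _ = phase_cross_correlation(
            ref, frames[i], upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift of frames[i] relative
        # to ref with opposite sign convention (shift to register onto ref)
        values[i] = -shift[axis_index]
    return MotionTrace(values=values, fps=video.fps, source=f"roi={roi} axis={axis}")


def fit_sinusoid_amplitude(trace: MotionTrace, freq: float) -> float:
    """Least-squares amplitude of a sinusoid at a known frequency.

    Fits ``a sin + b cos + c`` and returns ``sqrt(a^2 + b^2)``; robust to
    phase and to a constant offset, which makes it the preferred amplitude
    readout for bandpassed motion signals.
    """
    t = trace.times()
    design = np.column_stack(
        [
            np.sin(2.0 * np.pi * freq * t),
            np.cos(2.0 * np.pi * freq * t),
            np.ones_like(t),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, np.asarray(trace.values, dtype=np.float64), rcond=None)
    return float(np.hypot(coef[0], coef[1]))


@dataclass
class BreathRateResult:
    """Breath-rate estimate; ``detected=False`` means no respiration found."""

    detected: bool
    freq_hz: Optional[float] = None
    bpm: Optional[float] = None

    def __str__(self) -> str:
        if not self.detected:
            return "no respiration detected"
        return f"{self.bpm:.1f} breaths/min ({self.freq_hz:.3f} Hz)"


def estimate_breath_rate(
    trace: MotionTrace,
    band: Tuple[float, float] = (0.1, 0.5),
    prominence_factor: float = 4.0,
    min_amplitude: float = 0.01,
) -> BreathRateResult:
    """Periodogram peak of a motion trace restricted to the breathing band.

    The trace is mean-removed and Hann-tapered before the periodogram.  A
    respiration is reported only when the in-band peak power exceeds
    ``prominence_factor`` times the median in-band power *and* the implied
    oscillation amplitude exceeds ``min_amplitude`` (same units as the
    trace) — the absolute floor rejects numerically quiet, flat traces.
    """
    values = np.asarray(trace.values, dtype=np.float64)
    if len(values) < 20 * trace.fps:
        raise DimensionError(
            f"trace of {len(values)} samples at {trace.fps} Hz is shorter than 20 s"
        )
    detrended = values - values.mean()
    freqs, power = sp_signal.periodogram(detrended, fs=trace.fps, window="hann")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        return BreathRateResult(detected=False)
    band_freqs, band_power = freqs[in_band], power[in_band]
    peak_idx = int(np.argmax(band_power))
    peak_power = band_power[peak_idx]
    floor = float(np.median(band_power))
    df = freqs[1] - freqs[0]
    peak_amplitude = float(np.sqrt(2.0 * peak_power * df))
    if peak_power < prominence_factor * floor or peak_amplitude < min_amplitude:
        return BreathRateResult(detected=False)
    f_peak = float(band_freqs[peak_idx])
    return BreathRateResult(detected=True, freq_hz=f_peak, bpm=60.0 * f_peak)
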