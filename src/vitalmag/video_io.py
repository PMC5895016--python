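"""Video input/output and run configuration.

Videos are held in memory as a :class:`VideoTensor`: an ordered stack of
``T`` frames of shape ``H x W x C`` with real-valued intensities on the
``[0, 1]`` scale plus the sampling rate ``fps`` (Hz).  All processing in the
toolkit happens on this internal scale; conversion to 0-255 occurs only in
the quality metrics and at 8-bit export.  Amplified intensities may
transiently leave ``[0, 1]`` during processing and are clipped only when a
video is written to disk.

The canonical lossless on-disk format is a zero-padded PNG frame sequence in
a directory, together with a JSON sidecar ``fps.json`` holding
``{"fps": <float>}``.  Frames are stored as 16-bit grayscale/RGB PNG, which
round-trips any tensor whose values lie on the 8-bit (or 16-bit)
quantization grid bit-exactly.  Standard containers (MP4/AVI) are supported
as a convenience when an ffmpeg-capable imageio plugin is available; they
are lossy and never used by the test suite.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import ConfigurationError, DimensionError, FormatError

__all__ = [
    "VideoTensor",
    "RunConfig",
    "read_video",
    "write_video",
    "validate_nyquist",
    "rgb_to_gray",
]

_SIDECAR_NAME = "fps.json"
_CONTAINER_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}

# ITU-R 709 luma weights, matching skimage.color.rgb2gray
_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class VideoTensor:
    """Ordered frame stack ``I(x, t)`` with its sampling rate.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W, C)``, real-valued, finite.
    fps:
        Sampling rate ``f_s`` in Hz, strictly positive.
    colorspace:
        ``"rgb"`` (C=3) or ``"gray"`` (C=1).
    """

    frames: np.ndarray
    fps: float
    colorspace: str = "rgb"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim == 3:  # (T, H, W) -> single channel
            frames = frames[..., np.newaxis]
        if frames.ndim != 4:
            raise DimensionError(
                f"frames must have shape (T, H, W, C); got ndim={frames.ndim}"
            )
        t, h, w, c = frames.shape
        if t < 2:
            raise DimensionError(f"a video needs at least 2 frames; got T={t}")
        if h < 8 or w < 8:
            raise DimensionError(f"frames must be at least 8x8 px; got {h}x{w}")
        if c not in (1, 3):
            raise DimensionError(f"channel count must be 1 or 3; got C={c}")
        if not np.all(np.isfinite(frames)):
            raise DimensionError("frame intensities must all be finite")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ConfigurationError(f"fps must be positive and finite; got {self.fps}")
        expected = "gray" if c == 1 else "rgb"
        if self.colorspace not in ("rgb", "gray"):
            raise ConfigurationError(f"unknown colorspace {self.colorspace!r}")
        if self.colorspace != expected:
            self.colorspace = expected
        self.frames = frames
        self.fps = float(self.fps)

    # -- convenience accessors ------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[3]

    @property
    def duration(self) -> float:
        """Length of the video in seconds."""
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.fps

    def with_frames(self, frames: np.ndarray) -> "VideoTensor":
        """New tensor with the same fps but different frame data."""
        cs = "gray" if (frames.ndim == 3 or frames.shape[-1] == 1) else "rgb"
        return VideoTensor(frames=frames, fps=self.fps, colorspace=cs)


def rgb_to_gray(frames: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame stack to single-channel luma (keeps a C axis)."""
    if frames.shape[-1] == 1:
        return frames
    return np.tensordot(frames, _GRAY_WEIGHTS, axes=([-1], [0]))[..., np.newaxis]


@dataclass
class RunConfig:
    """User-facing magnification parameters shared by both pipelines.

    ``alpha`` is the magnification factor; ``(f_l, f_h)`` the temporal
    passband in Hz; ``levels`` the pyramid depth; ``orientations`` applies to
    the phase-based method only; ``lambda_c`` is the spatial cutoff
    wavelength (px) below which the intensity method attenuates alpha.
    """

    method: str = "elvm"
    alpha: float = 10.0
    f_l: float = 0.2
    f_h: float = 0.3
    levels: Optional[int] = None
    orientations: int = 4
    lambda_c: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("elvm", "pbvm"):
            raise ConfigurationError(f"method must be 'elvm' or 'pbvm'; got {self.method!r}")
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ConfigurationError(f"alpha must be finite and >= 0; got {self.alpha}")
        if not (0 < self.f_l < self.f_h):
            raise ConfigurationError(
                f"need 0 < f_l < f_h; got f_l={self.f_l}, f_h={self.f_h}"
            )
        if self.levels is not None and self.levels < 1:
            raise ConfigurationError(f"levels must be >= 1; got {self.levels}")


def validate_nyquist(config: RunConfig, video: VideoTensor) -> RunConfig:
    """Check the sampling-rate criterion ``f_s > 2 * f_h``.

    The passband ceiling must lie strictly below the Nyquist frequency of
    the video, otherwise the motion of interest is not sampled adequately.
    Returns the config unchanged when valid.
    """
    nyquist = video.fps / 2.0
    if not config.f_h < nyquist:
        raise ConfigurationError(
            f"f_h={config.f_h} Hz violates the Nyquist-Shannon criterion at "
            f"fps={video.fps}: the frame rate must exceed {2 * config.f_h} Hz"
        )
    return config


# -- readers / writers --------------------------------------------------------


def _frame_files(directory: Path) -> list:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    return files


def _to_unit(arr: np.ndarray) -> np.ndarray:
    """Map an integer image to float64 on [0, 1]."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.asarray(arr, dtype=np.float64)


def read_video(
    path: os.PathLike,
    as_gray: bool = False,
    fps: Optional[float] = None,
) -> VideoTensor:
    """Read a video from a PNG frame-sequence directory or a container file.

    For sequences the frame rate is taken from the ``fps.json`` sidecar (a
    ``fps=`` argument overrides it); for containers it comes from the
    metadata.  Intensities are scaled to ``[0, 1]``.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")

    if path.is_dir():
        files = _frame_files(path)
        if not files:
            raise FormatError(f"no PNG frames found in {path}")
        frames = np.stack([_to_unit(iio.imread(f)) for f in files])
        if fps is None:
            sidecar = path / _SIDECAR_NAME
            if not sidecar.exists():
                raise FormatError(
                    f"frame sequence {path} has no {_SIDECAR_NAME} sidecar; "
                    "pass fps= explicitly"
                )
            fps = float(json.loads(sidecar.read_text())["fps"])
    else:
        if path.suffix.lower() not in _CONTAINER_SUFFIXES:
            raise FormatError(f"unrecognized video format: {path.suffix}")
        try:
            frames = np.stack([_to_unit(f) for f in iio.imiter(path)])
            if fps is None:
                meta = iio.immeta(path)
                fps = float(meta.get("fps", 0.0)) or None
        except FormatError:
            raise
        except Exception as exc:  # plugin missing or corrupt file
            raise FormatError(f"cannot read container {path}: {exc}") from exc
        if fps is None:
            raise FormatError(f"container {path} carries no frame-rate metadata")
        if frames.shape[0] == 0:
            raise FormatError(f"container {path} holds zero frames")

    if frames.ndim == 3:
        frames = frames[..., np.newaxis]
    if frames.shape[-1] == 4:  # drop alpha
        frames = frames[..., :3]
    if as_gray and frames.shape[-1] == 3:
        frames = rgb_to_gray(frames)
    colorspace = "gray" if frames.shape[-1] == 1 else "rgb"
    return VideoTensor(frames=frames, fps=fps, colorspace=colorspace)


def write_video(video: VideoTensor, path: os.PathLike, lossless: bool = True) -> Path:
    """Write a video; returns the output path.

    ``lossless=True`` writes a 16-bit PNG sequence plus ``fps.json`` into a
    directory — bit-exact for tensors on the 8-bit or 16-bit quantization
    grid.  ``lossless=False`` writes a standard container (requires an
    ffmpeg-capable imageio plugin; lossy).  Intensities are clipped to
    ``[0, 1]`` at this point only.
    """
    import imageio.v3 as iio

    path = Path(path)
    clipped = np.clip(video.frames, 0.0, 1.0)
    if lossless:
        try:
            path.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise FormatError(f"cannot create output directory {path}: {exc}") from exc
        # 16-bit PNG for grayscale; RGB falls back to 8-bit (PIL has no
        # 16-bit RGB mode).  Both are bit-exact on the 8-bit grid.
        if video.n_channels == 1:
            data = np.round(clipped * 65535.0).astype(np.uint16)
        else:
            data = np.round(clipped * 255.0).astype(np.uint8)
        width = max(6, len(str(video.n_frames)))
        for i in range(video.n_frames):
            frame = data[i, ..., 0] if video.n_channels == 1 else data[i]
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
        (path / _SIDECAR_NAME).write_text(json.dumps({"fps": video.fps}))
    else:
        data = np.round(clipped * 255.0).astype(np.uint8)
        if video.n_channels == 1:
            data = np.repeat(data, 3, axis=-1)
        try:
            iio.imwrite(path, data, fps=video.fps)
        except Exception as exc:
            raise FormatError(
                f"cannot write container {path} (is an ffmpeg plugin installed?): {exc}"
            ) from exc
    return path
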