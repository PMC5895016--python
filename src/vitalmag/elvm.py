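"""Eulerian Linear Video Magnification (intensity-based pipeline).

For a scene translating by a small ``delta(t)``, the intensity at a fixed
pixel obeys ``I(x, t) = f(x + delta(t)) ~ f(x) + delta(t) f'(x)`` to first
order.  Temporally bandpassing the per-pixel series of each Laplacian-
pyramid band isolates ``delta(t) f'(x)`` for motion inside the passband;
adding it back scaled by ``alpha`` synthesizes a video whose motion is
``(1 + alpha)`` times the original:

    output(x, t) = I(x, t) + alpha * B(x, t)

where ``B`` is the bandpassed band signal.  This current-frame form is the
standard Eulerian synthesis; the literal first-frame Taylor form
``I(x, 0) + (1 + alpha) * B(x, t)`` is equivalent to first order and is
available behind ``exact_eq1_mode`` for comparison.

The linearization only holds while ``(1 + alpha) * delta`` stays below
about an eighth of the spatial wavelength of a band, which yields the
per-band magnification ceiling ``alpha <= lambda / (8 delta) - 1``.  The
pipeline can attenuate ``alpha`` linearly below a cutoff wavelength
``lambda_c`` and/or hard-enforce the ceiling per band.  Each RGB channel
is processed independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .errors import ConfigurationError
from .pyramids import (
    LaplacianPyramid,
    build_laplacian_pyramid,
    collapse_laplacian,
    default_levels,
)
from .temporal_filtering import apply_bandpass_stack, design_bandpass
from .video_io import RunConfig, VideoTensor, validate_nyquist

__all__ = ["ElvmConfig", "alpha_bound", "band_alpha", "magnify_intensity"]


@dataclass
class ElvmConfig:
    """Parameters of the intensity-based pipeline.

    ``lambda_c`` (px): bands with representative wavelength below this
    cutoff get ``alpha`` ramped down linearly; ``0`` disables attenuation.
    ``delta_assumed`` (px): motion scale used when ``enforce_bound`` caps
    each band's alpha at its linearization ceiling.  ``order`` is the
    Butterworth order of the temporal filter.
    """

    alpha: float = 10.0
    f_l: float = 0.2
    f_h: float = 0.3
    levels: Optional[int] = None
    lambda_c: float = 0.0
    delta_assumed: float = 1.0
    enforce_bound: bool = False
    exact_eq1_mode: bool = False
    order: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ConfigurationError(f"alpha must be finite and >= 0; got {self.alpha}")
        if self.delta_assumed < 0:
            raise ConfigurationError(f"delta_assumed must be >= 0; got {self.delta_assumed}")
        if self.levels is not None and self.levels < 1:
            raise ConfigurationError(f"levels must be >= 1; got {self.levels}")


def alpha_bound(lambda_k: float, delta: float) -> float:
    """Largest alpha keeping ``(1 + alpha) delta <= lambda / 8``.

    Returns ``lambda / (8 delta) - 1`` (may be negative when even the
    original motion breaks the linearization); unbounded for ``delta = 0``.
    """
    if lambda_k <= 0:
        raise ConfigurationError(f"lambda_k must be > 0; got {lambda_k}")
    if delta < 0:
        raise ConfigurationError(f"delta must be >= 0; got {delta}")
    if delta == 0:
        return float("inf")
    return lambda_k / (8.0 * delta) - 1.0


def band_alpha(alpha: float, lambda_k: float, lambda_c: float) -> float:
    """Applied per-band alpha: full above ``lambda_c``, linear ramp below."""
    if lambda_k <= 0:
        raise ConfigurationError(f"lambda_k must be > 0; got {lambda_k}")
    if lambda_c <= 0 or lambda_k >= lambda_c:
        return alpha
    return alpha * (lambda_k / lambda_c)


def band_alphas(config: ElvmConfig, pyr: LaplacianPyramid) -> List[float]:
    """Per-band applied alphas for a given pyramid structure."""
    alphas = []
    for lam in pyr.lambdas[: pyr.n_bands]:
        a_k = band_alpha(config.alpha, lam, config.lambda_c)
        if config.enforce_bound:
            a_k = min(a_k, max(0.0, alpha_bound(lam, config.delta_assumed)))
        alphas.append(a_k)
    return alphas


def magnify_intensity(video: VideoTensor, config: ElvmConfig) -> VideoTensor:
    """Run the intensity-based magnification pipeline on a video.

    Per channel: build a Laplacian pyramid of every frame, temporally
    bandpass each band's per-pixel series, scale by the per-band alpha and
    add back, then collapse.  The lowpass residual (scene DC and
    illumination) passes through unmodified.  Output intensities are not
    clipped — clipping happens only at write time.
    """
    validate_nyquist(
        RunConfig(method="elvm", alpha=config.alpha, f_l=config.f_l, f_h=config.f_h),
        video,
    )
    spec = design_bandpass(config.f_l, config.f_h, video.fps, order=config.order)
    if video.n_frames < spec.min_length():
        raise ConfigurationError(
            f"video of {video.n_frames} frames is too short for the temporal filter"
        )
    levels = config.levels
    if levels is None:
        levels = default_levels(video.height, video.width)

    out = np.empty_like(video.frames)
    for c in range(video.n_channels):
        pyramids = [
            build_laplacian_pyramid(video.frames[t, :, :, c], levels)
            for t in range(video.n_frames)
        ]
        alphas = band_alphas(config, pyramids[0])
        for k, a_k in enumerate(alphas):
            stack = np.stack([p.bands[k] for p in pyramids])
            if a_k == 0.0:
                continue
            filtered = apply_bandpass_stack(stack, spec, axis=0)
            if config.exact_eq1_mode:
                base = stack[0]
                for t, p in enumerate(pyramids):
                    p.bands[k] = base + (1.0 + a_k) * filtered[t]
            else:
                for t, p in enumerate(pyramids):
                    p.bands[k] = stack[t] + a_k * filtered[t]
        for t, p in enumerate(pyramids):
            out[t, :, :, c] = collapse_laplacian(p)
    return video.with_frames(out)
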