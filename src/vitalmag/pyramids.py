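"""Spatial multi-scale decompositions.

Two families are provided:

* **Gaussian / Laplacian pyramids** for the intensity-based magnification
  path.  Levels are produced by blurring with the separable 5-tap binomial
  kernel ``[1, 4, 6, 4, 1]/16`` (reflect boundary) and decimating by 2; a
  Laplacian band is the difference between a Gaussian level and the
  upsampled next-coarser level, which makes the transform exactly
  invertible.

* **Complex steerable pyramids** for the phase-based path.  The transform
  is built in the Fourier domain from raised-cosine radial windows (one
  octave of transition) and ``cos^(K-1)`` angular windows restricted to the
  positive-frequency half-plane, so every oriented band is analytic and its
  coefficients carry a local amplitude and a local phase.  The window set
  tiles the frequency plane (squared filters sum to one), so reconstruction
  from the real part of the bands plus the two residuals is exact up to
  floating-point rounding for even image dimensions.

Bands at scale ``s`` are stored downsampled by ``2^s`` (the Fourier support
of the recursive lowpass fits in the cropped spectrum, so no information is
lost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate1d

from .errors import DimensionError, StructureError

__all__ = [
    "LaplacianPyramid",
    "SteerableDecomposition",
    "build_gaussian_pyramid",
    "build_laplacian_pyramid",
    "collapse_laplacian",
    "build_steerable",
    "reconstruct_steerable",
    "amplitude_phase",
    "default_levels",
]

# ---------------------------------------------------------------------------
# Gaussian / Laplacian pyramids
# ---------------------------------------------------------------------------

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _blur(image: np.ndarray) -> np.ndarray:
    out = correlate1d(image, _BINOMIAL5, axis=0, mode="reflect")
    return correlate1d(out, _BINOMIAL5, axis=1, mode="reflect")


def _downsample2(image: np.ndarray) -> np.ndarray:
    """Blur then keep every other sample; output size is ceil(n/2)."""
    return _blur(image)[::2, ::2]


def _upsample2(image: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Zero-insert to ``shape`` then blur with the doubled kernel.

    The small image is symmetric-padded by one sample before insertion so
    border samples interpolate against reflected neighbours (a constant
    image upsamples to a constant, edge rows included).
    """
    padded = np.pad(image, 1, mode="symmetric")
    comb = np.zeros((2 * padded.shape[0] - 1, 2 * padded.shape[1] - 1), dtype=image.dtype)
    comb[::2, ::2] = padded
    comb = correlate1d(comb, 2.0 * _BINOMIAL5, axis=0, mode="constant")
    comb = correlate1d(comb, 2.0 * _BINOMIAL5, axis=1, mode="constant")
    return comb[2 : 2 + shape[0], 2 : 2 + shape[1]]


def default_levels(height: int, width: int, min_size: int = 16) -> int:
    """Deepest pyramid whose coarsest level keeps both dimensions >= min_size."""
    levels = 1
    h, w = height, width
    while min(h, w) // 2 >= min_size:
        h, w = (h + 1) // 2, (w + 1) // 2
        levels += 1
    return levels


def _check_pyramid_pre(image: np.ndarray, levels: int) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D image; got ndim={image.ndim}")
    if levels < 1:
        raise DimensionError(f"levels must be >= 1; got {levels}")
    min_dim = min(image.shape)
    if min_dim < 2 ** (levels - 1):
        raise DimensionError(
            f"image of shape {image.shape} is too small for {levels} levels"
        )
    return image


def build_gaussian_pyramid(image: np.ndarray, levels: int) -> List[np.ndarray]:
    """Successively blur and decimate; level 0 is the input itself."""
    image = _check_pyramid_pre(image, levels)
    pyramid = [image]
    for _ in range(levels - 1):
        pyramid.append(_downsample2(pyramid[-1]))
    return pyramid


@dataclass
class LaplacianPyramid:
    """Band-pass images ``H_k`` (full resolution first) plus lowpass residual.

    ``lambdas[k]`` is the representative spatial wavelength of band ``k``,
    taken as the diagonal length (px) of the level-k image; the residual's
    diagonal is appended last.
    """

    bands: List[np.ndarray]
    residual: np.ndarray
    lambdas: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lambdas:
            self.lambdas = [float(np.hypot(*b.shape)) for b in self.bands]
            self.lambdas.append(float(np.hypot(*self.residual.shape)))

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def build_laplacian_pyramid(image: np.ndarray, levels: int) -> LaplacianPyramid:
    """Laplacian pyramid with ``levels - 1`` difference bands and a residual.

    ``H_k = G_k - upsample2(G_{k+1})``; the residual is the coarsest
    Gaussian level, which makes the decomposition exactly invertible.
    """
    gaussian = build_gaussian_pyramid(image, levels)
    bands = [
        gaussian[k] - _upsample2(gaussian[k + 1], gaussian[k].shape)
        for k in range(levels - 1)
    ]
    return LaplacianPyramid(bands=bands, residual=gaussian[-1])


def collapse_laplacian(pyr: LaplacianPyramid) -> np.ndarray:
    """Invert :func:`build_laplacian_pyramid` (exact, coarse to fine)."""
    image = pyr.residual
    for band in reversed(pyr.bands):
        expected = ((band.shape[0] + 1) // 2, (band.shape[1] + 1) // 2)
        if band.ndim != 2 or expected != image.shape:
            raise StructureError(
                f"band of shape {band.shape} cannot follow level of shape {image.shape}"
            )
        image = band + _upsample2(image, band.shape)
    return image


# ---------------------------------------------------------------------------
# Complex steerable pyramid
# ---------------------------------------------------------------------------


def _freq_grids(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Radius (Nyquist = 1) and angle grids, fftshifted (DC at centre)."""
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h)) * 2.0
    fx = np.fft.fftshift(np.fft.fftfreq(w)) * 2.0
    gy, gx = np.meshgrid(fy, fx, indexing="ij")
    radius = np.hypot(gy, gx)
    angle = np.arctan2(gy, gx)
    return radius, angle


def _lowpass_window(radius: np.ndarray) -> np.ndarray:
    """Raised-cosine lowpass: 1 below r=1/2, 0 above r=1 (log-radius ramp)."""
    with np.errstate(divide="ignore"):
        log_r = np.log2(np.maximum(radius, 1e-12))
    ramp = np.clip(log_r + 1.0, 0.0, 1.0)
    return np.cos(ramp * np.pi / 2.0)


def _highpass_window(radius: np.ndarray) -> np.ndarray:
    low = _lowpass_window(radius)
    return np.sqrt(np.maximum(0.0, 1.0 - low * low))


def _angular_constant(n_orientations: int) -> float:
    k = n_orientations
    return math.sqrt(4.0 ** (k - 1) / (k * math.comb(2 * k - 2, k - 1)))


def _angular_window(angle: np.ndarray, k: int, n_orientations: int) -> np.ndarray:
    """Positive-lobe ``cos^(K-1)`` window for orientation ``k`` (half-plane)."""
    a_k = _angular_constant(n_orientations)
    theta = np.mod(angle - np.pi * k / n_orientations + np.pi, 2.0 * np.pi) - np.pi
    window = np.zeros_like(angle)
    lobe = np.abs(theta) < np.pi / 2.0
    window[lobe] = a_k * np.cos(theta[lobe]) ** (n_orientations - 1)
    return window


def _angular_window_full(angle: np.ndarray, k: int, n_orientations: int) -> np.ndarray:
    """Both-lobe magnitude window: ``a_K * |cos|^(K-1)``; squares tile to 1."""
    a_k = _angular_constant(n_orientations)
    return a_k * np.abs(np.cos(angle - np.pi * k / n_orientations)) ** (
        n_orientations - 1
    )


def _crop_center(dft: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Crop an fftshifted spectrum; rescales so decimation keeps amplitude."""
    h, w = dft.shape
    h2, w2 = shape
    y0 = h // 2 - h2 // 2
    x0 = w // 2 - w2 // 2
    return dft[y0 : y0 + h2, x0 : x0 + w2] * (h2 * w2) / (h * w)


def _pad_center(dft: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Zero-pad an fftshifted spectrum; exact inverse of :func:`_crop_center`."""
    h2, w2 = dft.shape
    h, w = shape
    out = np.zeros(shape, dtype=np.result_type(dft, np.complex128))
    y0 = h // 2 - h2 // 2
    x0 = w // 2 - w2 // 2
    out[y0 : y0 + h2, x0 : x0 + w2] = dft * (h * w) / (h2 * w2)
    return out


@dataclass
class SteerableDecomposition:
    """Complex steerable-pyramid coefficients.

    ``coeffs[s][o]`` is the complex coefficient array ``S_w = A_w e^{i phi}``
    at scale ``s`` (0 = finest, stored at size ``/2^s``) and orientation
    ``o``.  ``omega[s]`` is the representative radial spatial frequency of
    scale ``s`` in radians/px at the original image scale.  The real
    ``highpass_residual`` (full resolution) and ``lowpass_residual``
    (coarsest) complete the transform.
    """

    coeffs: List[List[np.ndarray]]
    highpass_residual: np.ndarray
    lowpass_residual: np.ndarray
    omega: List[float]
    shape: Tuple[int, int]
    n_orientations: int

    @property
    def n_scales(self) -> int:
        return len(self.coeffs)


def build_steerable(
    image: np.ndarray, scales: int, orientations: int
) -> SteerableDecomposition:
    """Frequency-domain complex steerable pyramid of a 2-D image.

    Each oriented band is analytic (built from the positive-frequency
    half-plane only), so ``abs`` and ``angle`` of its coefficients give the
    local amplitude and local phase used by phase-based magnification.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D image; got ndim={image.ndim}")
    if scales < 1:
        raise DimensionError(f"scales must be >= 1; got {scales}")
    if orientations < 1:
        raise DimensionError(f"orientations must be >= 1; got {orientations}")
    if min(image.shape) < 2 ** (scales + 2):
        raise DimensionError(
            f"image of shape {image.shape} is too small for {scales} scales"
        )

    dft = np.fft.fftshift(np.fft.fft2(image))
    radius, angle = _freq_grids(image.shape)
    highpass = np.real(
        np.fft.ifft2(np.fft.ifftshift(dft * _highpass_window(radius)))
    )
    lodft = dft * _lowpass_window(radius)

    coeffs: List[List[np.ndarray]] = []
    omega: List[float] = []
    for s in range(scales):
        radius, angle = _freq_grids(lodft.shape)
        band_hi = _highpass_window(2.0 * radius)
        scale_bands = []
        for o in range(orientations):
            mask = band_hi * 2.0 * _angular_window(angle, o, orientations)
            scale_bands.append(np.fft.ifft2(np.fft.ifftshift(lodft * mask)))
        coeffs.append(scale_bands)
        # band s spans radii [1/4, 1] of the current grid; its geometric
        # centre is r=1/2, i.e. pi/2^(s+1) rad/px at the original scale
        omega.append(np.pi / 2.0 ** (s + 1))
        lodft = _crop_center(
            lodft * _lowpass_window(2.0 * radius),
            ((lodft.shape[0] + 1) // 2, (lodft.shape[1] + 1) // 2),
        )

    lowpass = np.real(np.fft.ifft2(np.fft.ifftshift(lodft)))
    return SteerableDecomposition(
        coeffs=coeffs,
        highpass_residual=highpass,
        lowpass_residual=lowpass,
        omega=omega,
        shape=image.shape,
        n_orientations=orientations,
    )


def reconstruct_steerable(dec: SteerableDecomposition) -> np.ndarray:
    """Invert :func:`build_steerable` via the conjugate Fourier filters.

    The real part of each analytic band corresponds to the both-lobe
    (magnitude) angular filter, so summing ``fft(Re S) * B_s * |A_o|`` over
    bands and adding the residual branches reproduces the image exactly
    when the window set tiles (even dimensions).
    """
    expected_scales = len(dec.coeffs)
    lodft = np.fft.fftshift(np.fft.fft2(np.asarray(dec.lowpass_residual, dtype=np.float64)))
    for s in range(expected_scales - 1, -1, -1):
        bands = dec.coeffs[s]
        if len(bands) != dec.n_orientations:
            raise StructureError(
                f"scale {s} has {len(bands)} orientation bands; "
                f"expected {dec.n_orientations}"
            )
        shape = bands[0].shape
        radius, angle = _freq_grids(shape)
        band_hi = _highpass_window(2.0 * radius)
        acc = _pad_center(lodft, shape) * _lowpass_window(2.0 * radius)
        for o, band in enumerate(bands):
            if band.shape != shape:
                raise StructureError(
                    f"inconsistent band shapes at scale {s}: {band.shape} vs {shape}"
                )
            band_dft = np.fft.fftshift(np.fft.fft2(np.real(band)))
            acc = acc + band_dft * band_hi * _angular_window_full(
                angle, o, dec.n_orientations
            )
        lodft = acc

    if lodft.shape != dec.shape:
        raise StructureError(
            f"decomposition shape {dec.shape} does not match band structure"
        )
    radius, _ = _freq_grids(dec.shape)
    hi_dft = np.fft.fftshift(np.fft.fft2(np.asarray(dec.highpass_residual, dtype=np.float64)))
    out_dft = lodft * _lowpass_window(radius) + hi_dft * _highpass_window(radius)
    return np.real(np.fft.ifft2(np.fft.ifftshift(out_dft)))


def dump_bands(dec, directory) -> list:
    """Write every band of a decomposition as a normalized 8-bit PNG.

    Debug aid for visual inspection (contact-sheet style).  Accepts either
    a :class:`LaplacianPyramid` or a :class:`SteerableDecomposition`;
    returns the written paths.
    """
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _save(name: str, image: np.ndarray) -> "Path":
        image = np.abs(image) if np.iscomplexobj(image) else np.asarray(image)
        span = np.ptp(image)
        norm = (image - image.min()) / span if span > 0 else np.zeros_like(image)
        path = directory / f"{name}.png"
        iio.imwrite(path, np.round(255.0 * norm).astype(np.uint8))
        return path

    written = []
    if isinstance(dec, LaplacianPyramid):
        for k, band in enumerate(dec.bands):
            written.append(_save(f"band_{k}", band))
        written.append(_save("residual", dec.residual))
    elif isinstance(dec, SteerableDecomposition):
        for s, scale in enumerate(dec.coeffs):
            for o, band in enumerate(scale):
                written.append(_save(f"scale_{s}_orient_{o}", band))
        written.append(_save("highpass_residual", dec.highpass_residual))
        written.append(_save("lowpass_residual", dec.lowpass_residual))
    else:
        raise StructureError(f"cannot dump object of type {type(dec).__name__}")
    return written


def amplitude_phase(coeff_array: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Modulus and argument of complex coefficients.

    The phase lies in ``(-pi, pi]``; a zero coefficient has amplitude 0 and
    phase 0 by convention.
    """
    coeff_array = np.asarray(coeff_array)
    phase = np.angle(coeff_array)
    # np.angle maps a negative-zero imaginary part to -pi; fold onto +pi
    phase = np.where(phase == -np.pi, np.pi, phase)
    return np.abs(coeff_array), phase
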