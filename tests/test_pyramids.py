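"""Pyramid construction, perfect reconstruction and band placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalmag.errors import DimensionError, StructureError
from vitalmag.pyramids import (
    LaplacianPyramid,
    amplitude_phase,
    build_gaussian_pyramid,
    build_laplacian_pyramid,
    build_steerable,
    collapse_laplacian,
    default_levels,
    reconstruct_steerable,
)

KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _psnr(a, b):
    err = np.mean((255.0 * (a - b)) ** 2)
    return np.inf if err == 0 else 10.0 * np.log10(255.0**2 / err)


class TestGaussianPyramid:
    def test_constant_image_stays_constant(self):
        pyr = build_gaussian_pyramid(np.full((32, 32), 0.5), 3)
        for level in pyr:
            np.testing.assert_allclose(level, 0.5, atol=1e-12)

    def test_level_shapes_use_ceil_halving(self, rng):
        pyr = build_gaussian_pyramid(rng.random((64, 48)), 3)
        assert [p.shape for p in pyr] == [(64, 48), (32, 24), (16, 12)]

    def test_impulse_matches_direct_convolution_oracle(self):
        """Level 1 of a centered impulse equals brute-force blur+decimate."""
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        # independent oracle: explicit 2-D convolution with reflected borders
        # (numpy's "symmetric" duplicates the edge sample, matching the
        # pyramid's boundary rule)
        padded = np.pad(img, 2, mode="symmetric")
        blurred = np.zeros_like(img)
        k2d = np.outer(KERNEL, KERNEL)
        for i in range(16):
            for j in range(16):
                blurred[i, j] = np.sum(padded[i : i + 5, j : j + 5] * k2d[::-1, ::-1])
        expected = blurred[::2, ::2]
        level1 = build_gaussian_pyramid(img, 2)[1]
        np.testing.assert_allclose(level1, expected, atol=1e-14)

    def test_too_many_levels_raises(self):
        with pytest.raises(DimensionError):
            build_gaussian_pyramid(np.zeros((16, 16)), 6)

    def test_default_levels_keeps_coarsest_reasonable(self):
        levels = default_levels(96, 96)
        coarsest = 96 // 2 ** (levels - 1)
        assert coarsest >= 16
        assert 96 // 2**levels < 16


class TestLaplacianPyramid:
    def test_constant_image_has_empty_bands(self):
        pyr = build_laplacian_pyramid(np.full((32, 32), 0.5), 3)
        for band in pyr.bands:
            assert np.abs(band).max() < 1e-12
        np.testing.assert_allclose(pyr.residual, 0.5, atol=1e-12)

    def test_build_collapse_is_identity(self, rng):
        for _ in range(10):
            img = rng.random((64, 64))
            rec = collapse_laplacian(build_laplacian_pyramid(img, 4))
            assert np.abs(rec - img).max() < 1e-10

    def test_first_band_matches_stepwise_oracle(self, rng):
        """H_0 equals G_0 - upsample(blur-decimate(G_0)) built independently."""
        img = rng.random((32, 32))
        pyr = build_laplacian_pyramid(img, 2)
        from vitalmag.pyramids import _downsample2, _upsample2

        g1 = _downsample2(img)
        np.testing.assert_allclose(pyr.bands[0], img - _upsample2(g1, img.shape), atol=1e-14)
        np.testing.assert_allclose(pyr.residual, g1, atol=1e-14)

    def test_residual_only_collapse_preserves_mean(self, rng):
        """Zeroed bands leave a lowpass approximation with ~the input mean.

        The reflect-boundary blur redistributes border weight, so the mean
        is preserved to ~1e-3, not exactly (verified numerically).
        """
        img = rng.random((64, 64))
        pyr = build_laplacian_pyramid(img, 4)
        lowpassed = collapse_laplacian(
            LaplacianPyramid(
                bands=[np.zeros_like(b) for b in pyr.bands], residual=pyr.residual
            )
        )
        assert abs(lowpassed.mean() - img.mean()) < 5e-3

    def test_linearity(self, rng):
        i, j = rng.random((64, 64)), rng.random((64, 64))
        pa = build_laplacian_pyramid(2.0 * i + 3.0 * j, 3)
        pi = build_laplacian_pyramid(i, 3)
        pj = build_laplacian_pyramid(j, 3)
        for ba, bi, bj in zip(pa.bands, pi.bands, pj.bands):
            np.testing.assert_allclose(ba, 2.0 * bi + 3.0 * bj, atol=1e-8)

    def test_lambda_is_level_diagonal(self, rng):
        pyr = build_laplacian_pyramid(rng.random((64, 48)), 3)
        np.testing.assert_allclose(
            pyr.lambdas[:2], [np.hypot(64, 48), np.hypot(32, 24)]
        )

    def test_collapse_rejects_mismatched_shapes(self, rng):
        pyr = build_laplacian_pyramid(rng.random((32, 32)), 3)
        bad = LaplacianPyramid(bands=list(reversed(pyr.bands)), residual=pyr.residual)
        with pytest.raises(StructureError):
            collapse_laplacian(bad)


class TestSteerablePyramid:
    def test_constant_image_energy_in_lowpass(self):
        dec = build_steerable(np.full((64, 64), 0.5), 2, 4)
        for scale in dec.coeffs:
            for band in scale:
                assert np.abs(band).max() < 1e-12
        assert abs(dec.lowpass_residual.mean() - 0.5) < 1e-12

    def test_band_count_two_scales_six_orientations(self):
        """A 2-scale, 6-orientation decomposition yields 12 oriented bands."""
        x = np.linspace(-1, 1, 64)
        circle = (np.add.outer(x**2, x**2) < 0.25).astype(float)
        dec = build_steerable(circle, 2, 6)
        assert sum(len(scale) for scale in dec.coeffs) == 12
        assert dec.highpass_residual.shape == (64, 64)
        assert dec.lowpass_residual.shape == (16, 16)

    @pytest.mark.parametrize("scales,orients", [(2, 4), (3, 4), (2, 8)])
    def test_reconstruction_fidelity(self, rng, scales, orients):
        for _ in range(5):
            img = rng.random((64, 64))
            rec = reconstruct_steerable(build_steerable(img, scales, orients))
            assert _psnr(img, rec) > 40.0

    def test_constant_reconstructs_exactly(self):
        img = np.full((64, 64), 0.3)
        rec = reconstruct_steerable(build_steerable(img, 2, 4))
        assert np.abs(rec - img).max() < 1e-8

    def test_zeroing_highpass_residual_lowers_psnr(self, rng):
        img = rng.random((64, 64))
        dec = build_steerable(img, 2, 4)
        full = _psnr(img, reconstruct_steerable(dec))
        dec.highpass_residual = np.zeros_like(dec.highpass_residual)
        assert _psnr(img, reconstruct_steerable(dec)) < full

    @pytest.mark.parametrize("orientation", [0, 1, 2, 3])
    def test_oriented_sinusoid_lands_in_matching_band(self, orientation):
        """A grating at band center frequency puts most energy in its band.

        Adjacent cos^(K-1) windows overlap by construction, so the matching
        band holds the plurality (not >90%) of the energy.
        """
        k_orients = 4
        theta = np.pi * orientation / k_orients
        omega = np.pi / 2.0  # radial centre of the finest scale
        xx, yy = np.meshgrid(np.arange(64), np.arange(64))
        grating = np.cos(omega * (np.cos(theta) * xx + np.sin(theta) * yy))
        dec = build_steerable(grating, 2, k_orients)
        energy = np.array(
            [[np.sum(np.abs(b) ** 2) for b in scale] for scale in dec.coeffs]
        )
        s_best, o_best = np.unravel_index(np.argmax(energy), energy.shape)
        assert (s_best, o_best) == (0, orientation)
        assert energy[s_best, o_best] / energy.sum() > 0.5

    def test_linearity(self, rng):
        i, j = rng.random((64, 64)), rng.random((64, 64))
        da = build_steerable(2.0 * i + 3.0 * j, 2, 4)
        di = build_steerable(i, 2, 4)
        dj = build_steerable(j, 2, 4)
        for sa, si, sj in zip(da.coeffs, di.coeffs, dj.coeffs):
            for ba, bi, bj in zip(sa, si, sj):
                np.testing.assert_allclose(ba, 2.0 * bi + 3.0 * bj, atol=1e-8)

    def test_energy_non_creation(self, rng):
        """Total coefficient energy stays below a fixed multiple of the input."""
        for _ in range(5):
            img = rng.random((64, 64))
            dec = build_steerable(img, 3, 4)
            total = sum(np.sum(np.abs(b) ** 2) for sc in dec.coeffs for b in sc)
            total += np.sum(dec.highpass_residual**2)
            total += np.sum(dec.lowpass_residual**2)
            assert total <= 2.0 * np.sum(img**2)

    def test_image_too_small_raises(self):
        with pytest.raises(DimensionError):
            build_steerable(np.zeros((16, 16)), 3, 4)


class TestAmplitudePhase:
    def test_unit_imaginary(self):
        amp, phase = amplitude_phase(np.array([1j]))
        assert amp[0] == pytest.approx(1.0)
        assert phase[0] == pytest.approx(np.pi / 2)

    def test_zero_coefficient_convention(self):
        amp, phase = amplitude_phase(np.array([0.0 + 0.0j]))
        assert amp[0] == 0.0
        assert phase[0] == 0.0

    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_polar_round_trip(self, re, im):
        z = np.array([complex(re, im)])
        amp, phase = amplitude_phase(z)
        np.testing.assert_allclose(amp * np.exp(1j * phase), z, atol=1e-12)
        assert -np.pi < phase[0] <= np.pi
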