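"""Phase-based magnification: phase deltas, bounds, pipeline contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalmag.errors import ConfigurationError, StructureError
from vitalmag.evaluation import fit_sinusoid_amplitude, measure_displacement, psnr
from vitalmag.pbvm import PbvmConfig, magnify_phase, pbvm_alpha_bound, phase_differences
from vitalmag.pyramids import build_steerable
from vitalmag.synthetic_scenes import SceneSpec, generate_breathing_video
from vitalmag.video_io import VideoTensor


class TestPhaseDifferences:
    def test_identical_frames_give_zero(self, rng):
        img = rng.random((64, 64))
        dec = build_steerable(img, 2, 4)
        stack = phase_differences(dec, dec)
        for scale in stack.deltas:
            for deltas in scale:
                assert np.abs(deltas).max() < 1e-12

    def test_wrap_arithmetic(self):
        """Phases 3.0 and -3.0 differ by 6.0 wrapped into (-pi, pi]."""
        a = np.exp(1j * 3.0)
        b = np.exp(1j * -3.0)
        delta = np.angle(a * np.conj(b))
        assert delta == pytest.approx(6.0 - 2.0 * np.pi, abs=1e-12)

    def test_translated_sinusoid_obeys_shift_theorem(self):
        """Translating a grating by d shifts its band phase by ~omega*d."""
        omega, d = np.pi / 2.0, 0.3
        xx = np.arange(64)[np.newaxis, :].repeat(64, axis=0).astype(float)
        frame0 = 0.5 + 0.2 * np.cos(omega * xx)
        frame1 = 0.5 + 0.2 * np.cos(omega * (xx - d))
        dec0 = build_steerable(frame0, 2, 4)
        dec1 = build_steerable(frame1, 2, 4)
        stack = phase_differences(dec1, dec0)
        # dominant band: finest scale, horizontal-frequency orientation 0
        band0 = stack.deltas[0][0]
        amp0 = np.abs(dec0.coeffs[0][0])
        # amplitude-weighted mean phase delta where the carrier is strong
        strong = amp0 > 0.5 * amp0.max()
        measured = np.mean(band0[strong])
        # the local phase at a fixed pixel is omega*(x - d): moving the
        # pattern toward +x lowers it, hence the minus sign
        assert measured == pytest.approx(-omega * d, rel=0.05)

    def test_structure_mismatch_raises(self, rng):
        img = rng.random((64, 64))
        with pytest.raises(StructureError):
            phase_differences(build_steerable(img, 2, 4), build_steerable(img, 3, 4))

    def test_deltas_lie_in_principal_branch(self, rng):
        d0 = build_steerable(rng.random((64, 64)), 2, 4)
        d1 = build_steerable(rng.random((64, 64)), 2, 4)
        for scale in phase_differences(d1, d0).deltas:
            for deltas in scale:
                assert np.all(deltas > -np.pi) and np.all(deltas <= np.pi)


class TestAlphaBound:
    @given(st.floats(0.01, np.pi), st.floats(0.001, 2.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_half_octave_doubles_octave_bound(self, omega, delta):
        assert pbvm_alpha_bound(omega, delta, "half_octave") == pytest.approx(
            2.0 * pbvm_alpha_bound(omega, delta, "octave")
        )

    def test_doubling_omega_halves_bound(self):
        assert pbvm_alpha_bound(0.5, 0.1) == pytest.approx(
            2.0 * pbvm_alpha_bound(1.0, 0.1)
        )

    def test_zero_motion_unbounded(self):
        assert pbvm_alpha_bound(1.0, 0.0) == np.inf

    def test_invalid_omega(self):
        with pytest.raises(ConfigurationError):
            pbvm_alpha_bound(0.0, 0.1)


class TestPbvmConfig:
    def test_orientation_presets_only(self):
        with pytest.raises(ConfigurationError):
            PbvmConfig(orientations=6)

    def test_bound_mode_must_match_orientations(self):
        with pytest.raises(ConfigurationError):
            PbvmConfig(orientations=8, bound_mode="octave")
        PbvmConfig(orientations=8, bound_mode="half_octave")  # valid


class TestMagnifyPhase:
    def test_alpha_zero_reconstruction_fidelity(self, short_blob_scene):
        _, video, _ = short_blob_scene
        out = magnify_phase(video, PbvmConfig(alpha=0.0, scales=3))
        assert psnr(video, out) > 35.0

    def test_amplification_factor_on_breathing_blob(self, short_blob_scene):
        spec, video, _ = short_blob_scene
        out = magnify_phase(video, PbvmConfig(alpha=19.0, scales=4))
        amp = fit_sinusoid_amplitude(measure_displacement(out), spec.freq)
        assert amp == pytest.approx((1.0 + 19.0) * spec.delta0, rel=0.25)

    def test_half_octave_preset_also_amplifies(self, short_blob_scene):
        spec, video, _ = short_blob_scene
        out = magnify_phase(
            video,
            PbvmConfig(alpha=19.0, scales=4, orientations=8, bound_mode="half_octave"),
        )
        amp = fit_sinusoid_amplitude(measure_displacement(out), spec.freq)
        assert amp == pytest.approx((1.0 + 19.0) * spec.delta0, rel=0.25)

    def test_amplitudes_preserved_by_rotation(self, rng):
        """Coefficient moduli are untouched; only phases move."""
        img = rng.random((64, 64))
        dec = build_steerable(img, 2, 4)
        rotation = np.exp(1j * rng.uniform(-np.pi, np.pi, size=dec.coeffs[0][0].shape))
        rotated = dec.coeffs[0][0].astype(np.complex64) * rotation.astype(np.complex64)
        before = np.abs(dec.coeffs[0][0])
        after = np.abs(rotated)
        rel = np.abs(after - before) / np.maximum(before, 1e-12)
        assert rel[before > 1e-6].max() < 1e-5  # single-precision rounding only

    def test_nonperiodic_shift_is_magnified(self):
        """A one-shot smooth shift inside the passband is amplified too."""
        spec = SceneSpec(duration=30.0, delta0=0.0)
        base, _ = generate_breathing_video(spec)
        t = np.arange(base.n_frames) / base.fps
        # logistic step of 0.05 px centred mid-clip, ~4 s rise (in-band energy)
        delta = 0.05 / (1.0 + np.exp(-(t - 15.0) / 1.2))
        from vitalmag.synthetic_scenes import _render_pattern

        frames = np.stack(
            [spec.background + _render_pattern(spec, (d, 0.0)) for d in delta]
        )[..., np.newaxis]
        video = VideoTensor(frames=frames, fps=spec.fps, colorspace="gray")
        out = magnify_phase(video, PbvmConfig(alpha=15.0, f_l=0.1, f_h=0.5, scales=4))
        disp_in = measure_displacement(video).values
        disp_out = measure_displacement(out).values
        # only the in-band part of the one-shot shift is amplified, so the
        # swing grows by a factor well above 1 but below (1 + alpha)
        assert np.ptp(disp_out) > 2.0 * np.ptp(disp_in)

    def test_nyquist_violation_rejected(self, short_blob_scene):
        _, video, _ = short_blob_scene
        with pytest.raises(ConfigurationError):
            magnify_phase(video, PbvmConfig(alpha=5.0, f_l=4.0, f_h=6.0))
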