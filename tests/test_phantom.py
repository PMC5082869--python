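"""Synthetic tissue phantom: structure, determinism, forward-model physics."""

import numpy as np
import pytest
from skimage.measure import label

from pseudohe import (
    OpticsConfig,
    PhantomSpec,
    generate_phantom,
    rms_demodulate,
    simulate_sim_frames,
)
from pseudohe.core import Channel, FlatFieldCalibration, normalize_16bit
from pseudohe.phantom import modulated_frames, vignetting_profile
from pseudohe.preprocess import flatfield_correct


class TestGeneratePhantom:
    def test_channel_specificity_of_the_stains(self, small_spec):
        scene = generate_phantom(small_spec)
        nuclei = scene.masks["nuclei"]
        assert np.all(scene.d5_truth[~nuclei] == 0)  # DRAQ5 only in nuclei
        assert np.all(scene.e_truth[nuclei] == 0)  # eosin-negative nuclei
        assert np.all(scene.e_truth[scene.masks["lumen"]] == 0)
        assert scene.d5_truth.min() >= 0 and scene.d5_truth.max() <= 1
        assert scene.e_truth.min() >= 0 and scene.e_truth.max() <= 1

    def test_requested_nucleus_count_matches_labeled_components(self, small_spec):
        scene = generate_phantom(small_spec)
        assert label(scene.masks["nuclei"]).max() == small_spec.n_nuclei

    def test_zero_nuclei_gives_empty_nuclear_plane(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__, "n_nuclei": 0})
        scene = generate_phantom(spec)
        assert np.all(scene.d5_truth == 0)

    def test_same_seed_is_bit_identical(self, small_spec):
        a = generate_phantom(small_spec)
        b = generate_phantom(small_spec)
        np.testing.assert_array_equal(a.d5_truth, b.d5_truth)
        np.testing.assert_array_equal(a.e_truth, b.e_truth)

    def test_infeasible_packing_raises(self):
        spec = PhantomSpec(image_shape=(48, 48), n_nuclei=200, n_lumina=0,
                           n_rows=1, n_cols=1, overlap_px=0, rng_seed=0)
        with pytest.raises(RuntimeError, match="pack"):
            generate_phantom(spec)


class TestModulatedFrames:
    def test_round_trip_recovers_modulation_amplitude(self, small_spec, rng):
        s = rng.uniform(0.1, 0.9, small_spec.image_shape)
        frames = modulated_frames(s, small_spec)
        out = rms_demodulate(frames)
        np.testing.assert_allclose(
            out.sectioned, small_spec.modulation_depth * s, rtol=1e-9
        )
        np.testing.assert_allclose(out.widefield, s, rtol=1e-9)

    def test_defocus_layer_scales_by_attenuation_factor(self, small_spec, rng):
        s_f = rng.uniform(0.1, 0.9, small_spec.image_shape)
        s_d = rng.uniform(0.1, 0.9, small_spec.image_shape)
        frames = modulated_frames(s_f, small_spec, defocus=s_d, attenuation=0.2)
        out = rms_demodulate(frames)
        m = small_spec.modulation_depth
        np.testing.assert_allclose(out.sectioned, m * (s_f + 0.2 * s_d), rtol=1e-9)
        np.testing.assert_allclose(out.widefield, s_f + s_d, rtol=1e-9)


def _sectioned_and_widefield(acq, channel):
    """Flat-field + demodulate one channel of a 1x1-tile acquisition."""
    calib = FlatFieldCalibration.from_raw(acq.calibrations[channel], channel)
    (fs,) = [f for f in acq.framesets if f.channel == channel]
    out = rms_demodulate(
        [flatfield_correct(normalize_16bit(f), calib) for f in fs.frames]
    )
    return out.sectioned, out.widefield


class TestSimulateSimFrames:
    def test_noiseless_round_trip_within_quantization(self, small_spec):
        spec = PhantomSpec(**{
            **small_spec.__dict__, "photon_budget": 0.0, "read_noise_sigma": 0.0,
            "defocus_intensity": 0.0,
        })
        scene = generate_phantom(spec)
        acq = simulate_sim_frames(scene.d5_truth, scene.e_truth, spec)
        sect, wide = _sectioned_and_widefield(acq, Channel.D5)
        expected = spec.modulation_depth * scene.d5_truth * acq.frame_scale
        np.testing.assert_allclose(sect, expected, atol=5e-5)
        np.testing.assert_allclose(
            wide, scene.d5_truth * acq.frame_scale, atol=5e-5
        )

    def test_same_seed_is_bit_identical(self, small_spec):
        scene = generate_phantom(small_spec)
        a = simulate_sim_frames(scene.d5_truth, scene.e_truth, small_spec)
        b = simulate_sim_frames(scene.d5_truth, scene.e_truth, small_spec)
        for fa, fb in zip(a.framesets, b.framesets):
            for x, y in zip(fa.frames, fb.frames):
                np.testing.assert_array_equal(x, y)

    def test_out_of_focus_layer_suppressed_by_axial_attenuation(self, small_spec):
        """Noiseless sectioning contract: the defocus layer appears in the
        sectioned image attenuated by exactly the theoretical a(z), in both
        channels (least-squares on the known in-focus/defocus planes)."""
        from scipy.ndimage import gaussian_filter

        spec = PhantomSpec(**{
            **small_spec.__dict__, "photon_budget": 0.0, "read_noise_sigma": 0.0,
        })
        scene = generate_phantom(spec)
        acq = simulate_sim_frames(scene.d5_truth, scene.e_truth, spec)
        for channel, truth in ((Channel.D5, scene.d5_truth), (Channel.E, scene.e_truth)):
            a_theory = acq.defocus_attenuation[channel]
            sect, _ = _sectioned_and_widefield(acq, channel)
            sect = sect / (spec.modulation_depth * acq.frame_scale)
            s_d = spec.defocus_intensity * gaussian_filter(
                truth, spec.defocus_blur_um / spec.pixel_size_um, mode="reflect"
            )
            sel = (truth + s_d) > 0.15
            coeffs, *_ = np.linalg.lstsq(
                np.column_stack([truth[sel], s_d[sel]]), sect[sel], rcond=None
            )
            assert coeffs[0] == pytest.approx(1.0, rel=0.02)
            assert coeffs[1] == pytest.approx(a_theory, rel=0.02)

    def test_shot_noise_scales_as_inverse_sqrt_photon_budget(self):
        base = dict(
            image_shape=(96, 96), n_nuclei=0, n_lumina=0, n_rows=1, n_cols=1,
            overlap_px=0, vignetting_strength=0.0, defocus_intensity=0.0,
            read_noise_sigma=0.0, rng_seed=3,
        )
        flat = np.full((96, 96), 0.5)
        ref_spec = PhantomSpec(**base, photon_budget=0.0)
        ref_acq = simulate_sim_frames(flat, flat, ref_spec)
        ref = normalize_16bit(ref_acq.framesets[0].frames[0])
        stds = []
        for budget in (10_000.0, 40_000.0):
            spec = PhantomSpec(**base, photon_budget=budget)
            acq = simulate_sim_frames(flat, flat, spec)
            frame = normalize_16bit(acq.framesets[0].frames[0])
            stds.append((frame - ref).std())  # noise only, modulation removed
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.1)

    def test_saturation_guard_trips(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__, "digital_gain": 5.0})
        scene = generate_phantom(spec)
        with pytest.raises(ValueError, match="saturate"):
            simulate_sim_frames(scene.d5_truth, scene.e_truth, spec)

    def test_calibration_is_vignetting_times_constant(self, small_spec):
        scene = generate_phantom(small_spec)
        acq = simulate_sim_frames(scene.d5_truth, scene.e_truth, small_spec)
        v = vignetting_profile(acq.layout.frame_shape, small_spec.vignetting_strength)
        expected = np.round(small_spec.calibration_level * v * 65535)
        np.testing.assert_array_equal(acq.calibrations[Channel.E], expected)


def test_widefield_simulation_has_single_frames(small_spec):
    from pseudohe import simulate_widefield_frames

    scene = generate_phantom(small_spec)
    acq = simulate_widefield_frames(scene.d5_truth, scene.e_truth, small_spec)
    assert all(len(fs.frames) == 1 for fs in acq.framesets)
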