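"""Data-model contracts: normalization, frame sets, calibrations, configs."""

import numpy as np
import pytest

from pseudohe import (
    ChannelImage,
    FlatFieldCalibration,
    MosaicLayout,
    RawFrameSet,
    RenderParams,
    normalize_16bit,
)
from pseudohe.core import Channel, AcquisitionMode, SIM_PHASES_RAD


class TestNormalize16Bit:
    @pytest.mark.parametrize(
        "value, expected",
        [(0, 0.0), (65535, 1.0), (32768, 32768 / 65535)],
    )
    def test_fixed_points(self, value, expected):
        out = normalize_16bit(np.full((4, 4), value, dtype=np.uint16))
        assert out.dtype == np.float64
        np.testing.assert_allclose(out, expected, rtol=0, atol=0)

    def test_monotone_and_bijective_on_all_levels(self):
        levels = np.arange(65536, dtype=np.uint16)
        out = normalize_16bit(levels)
        assert np.all(np.diff(out) > 0)  # strictly increasing
        assert np.unique(out).size == 65536  # no two levels collide
        assert out[0] == 0.0 and out[-1] == 1.0

    @pytest.mark.parametrize("dtype", [np.float32, np.int16, np.uint32])
    def test_rejects_non_16bit_unsigned(self, dtype):
        with pytest.raises(TypeError):
            normalize_16bit(np.zeros((2, 2), dtype=dtype))


class TestRawFrameSet:
    def _frames(self, n, shape=(8, 8)):
        return tuple(np.zeros(shape, dtype=np.uint16) for _ in range(n))

    def test_sim_requires_three_frames_with_canonical_phases(self):
        fs = RawFrameSet(self._frames(3), Channel.D5, AcquisitionMode.SIM)
        assert fs.phases_rad == pytest.approx(SIM_PHASES_RAD)
        with pytest.raises(ValueError):
            RawFrameSet(self._frames(1), Channel.D5, AcquisitionMode.SIM)
        with pytest.raises(ValueError):
            RawFrameSet(
                self._frames(3), Channel.D5, AcquisitionMode.SIM,
                phases_rad=(0.0, 1.0, 2.0),
            )

    def test_widefield_requires_single_frame(self):
        RawFrameSet(self._frames(1), Channel.E, AcquisitionMode.WIDEFIELD)
        with pytest.raises(ValueError):
            RawFrameSet(self._frames(3), Channel.E, AcquisitionMode.WIDEFIELD)

    def test_mismatched_shapes_rejected(self):
        frames = (
            np.zeros((8, 8), dtype=np.uint16),
            np.zeros((8, 9), dtype=np.uint16),
            np.zeros((8, 8), dtype=np.uint16),
        )
        with pytest.raises(ValueError):
            RawFrameSet(frames, Channel.D5, AcquisitionMode.SIM)


class TestChannelImage:
    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(ValueError):
            ChannelImage(np.array([[0.0, 1.5]]), Channel.D5)
        with pytest.raises(ValueError):
            ChannelImage(np.array([[-0.1, 0.5]]), Channel.D5)

    def test_accepts_unit_interval(self):
        img = ChannelImage(np.array([[0.0, 1.0], [0.3, 0.7]]), Channel.E)
        assert img.shape == (2, 2)


class TestFlatFieldCalibration:
    def test_floor_clamp_removes_dead_pixels(self):
        raw = np.full((10, 10), 30000, dtype=np.uint16)
        raw[0, 0] = 0  # dead pixel
        calib = FlatFieldCalibration.from_raw(raw, Channel.D5)
        assert np.all(calib.reference > 0)
        # dead pixel raised to the guard floor (half the median level)
        assert calib.reference[0, 0] == pytest.approx(15000 / 65535)
        assert calib.reference[1, 1] == pytest.approx(30000 / 65535)

    def test_smooth_vignetting_tail_not_clamped(self):
        yy, xx = np.mgrid[0:64, 0:64] / 64.0
        v = 0.8 * (1.0 - 0.3 * ((yy - 0.5) ** 2 + (xx - 0.5) ** 2))
        calib = FlatFieldCalibration.from_raw(v, Channel.D5)
        np.testing.assert_array_equal(calib.reference, v)

    def test_all_zero_calibration_rejected(self):
        with pytest.raises(ValueError):
            FlatFieldCalibration.from_raw(
                np.zeros((4, 4), dtype=np.uint16), Channel.E
            )

    def test_direct_construction_requires_positive(self):
        with pytest.raises(ValueError):
            FlatFieldCalibration(np.zeros((4, 4)), Channel.E)


class TestRenderParams:
    def test_defaults_match_operating_point(self):
        p = RenderParams()
        assert p.gamma_d5 == 0.85 and p.gamma_e == 0.75
        assert p.d5_rgb == (0.24, 0.21, 0.62)
        assert p.e_rgb == (0.88, 0.27, 0.66)

    @pytest.mark.parametrize("kwargs", [
        {"gamma_d5": 1.2}, {"gamma_e": 0.5}, {"scale_a": 5.0},
        {"scale_b": 0.5}, {"d5_rgb": (1.2, 0.2, 0.6)},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RenderParams(**kwargs)


class TestMosaicLayout:
    def test_mosaic_shape_accounts_for_overlap(self):
        layout = MosaicLayout(3, 2, (100, 80), (10, 5))
        assert layout.mosaic_shape == (3 * 100 - 2 * 10, 2 * 80 - 5)

    def test_overlap_must_be_smaller_than_frame(self):
        with pytest.raises(ValueError):
            MosaicLayout(2, 2, (50, 50), (50, 0))

    def test_origins_are_row_major_from_top_left(self):
        layout = MosaicLayout(2, 2, (10, 10), (2, 2))
        assert layout.origin_of((0, 0)) == (0, 0)
        assert layout.origin_of((1, 1)) == (8, 8)
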