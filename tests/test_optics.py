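"""Optical-sectioning theory: normalized frequency, axial response, HWHM."""

import numpy as np
import pytest

from pseudohe import (
    OpticsConfig,
    axial_response,
    channel_hwhm_um,
    hwhm,
    normalized_frequency,
)
from pseudohe.core import Channel
from pseudohe.optics import AxialResponseCurve


class TestNormalizedFrequency:
    @pytest.mark.parametrize(
        "lambda_nm, expected",
        [(470.0, 0.01786), (630.0, 0.02394)],  # 17.1e3 * lambda / 0.45
    )
    def test_instrument_values(self, lambda_nm, expected):
        nu = normalized_frequency(17.1, lambda_nm, 0.45)
        assert nu == pytest.approx(expected, abs=5e-6)

    def test_linear_in_wavelength_toward_zero(self):
        assert normalized_frequency(17.1, 1e-6, 0.45) == pytest.approx(0.0, abs=1e-10)

    def test_beyond_cutoff_rejected(self):
        with pytest.raises(ValueError):
            normalized_frequency(1000.0, 600.0, 0.45)  # nu > 1

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_frequency(-1.0, 470.0, 0.45)


class TestAxialResponse:
    def test_unity_at_focus_and_even_in_defocus(self):
        z = np.linspace(-60, 60, 241)
        curve = axial_response(0.02, 575.0, 0.45, z_grid_um=z)
        i0 = np.argmin(np.abs(z))
        assert curve.attenuation[i0] == pytest.approx(1.0)
        assert np.all(curve.attenuation <= 1.0 + 1e-12)
        np.testing.assert_allclose(curve.attenuation, curve.attenuation[::-1],
                                   rtol=0, atol=1e-12)

    def test_doubling_frequency_halves_hwhm_in_small_nu_regime(self):
        h1 = hwhm(axial_response(0.025, 575.0, 0.45))
        h2 = hwhm(axial_response(0.05, 575.0, 0.45))
        assert h1 / h2 == pytest.approx(2.0, rel=0.02)

    def test_invalid_nu_rejected(self):
        for nu in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                axial_response(nu, 575.0, 0.45)


class TestHwhm:
    def test_synthetic_triangular_curve(self):
        # attenuation = max(0, 1 - |z|/20) crosses 1/2 at z = 10 exactly
        z = np.linspace(-40, 40, 801)
        curve = AxialResponseCurve(
            nu=0.02, defocus_um=z, attenuation=np.maximum(0.0, 1 - np.abs(z) / 20)
        )
        assert hwhm(curve) == pytest.approx(10.0, abs=1e-9)

    def test_tabulated_curve_without_crossing_rejected(self):
        z = np.linspace(0, 1.0, 11)
        curve = AxialResponseCurve(nu=0.02, defocus_um=z,
                                   attenuation=np.full_like(z, 0.9))
        with pytest.raises(ValueError):
            hwhm(curve)

    def test_analytic_solution_meets_half_maximum(self):
        curve = axial_response(0.0218, 575.0, 0.45)
        z_half = hwhm(curve)
        assert z_half > 0
        assert float(curve.evaluate(np.array([z_half]))[0]) == pytest.approx(0.5, abs=1e-3)

    def test_monotone_decreasing_in_grid_frequency(self, default_optics):
        # nu spanning (0, 0.5]: finer grids -> thinner sections
        freqs = [5.0, 17.1, 60.0, 150.0, 300.0, 390.0]  # nu up to ~0.5 at 575 nm
        widths = [
            channel_hwhm_um(
                OpticsConfig(grid_freq_cycles_per_mm=f), Channel.E
            )
            for f in freqs
        ]
        assert np.all(np.diff(widths) < 0)

    def test_widefield_limit_is_unbounded(self):
        # nu -> 0: no sectioning; width grows without bound
        coarse = channel_hwhm_um(OpticsConfig(grid_freq_cycles_per_mm=0.171), Channel.E)
        base = channel_hwhm_um(OpticsConfig(grid_freq_cycles_per_mm=17.1), Channel.E)
        assert coarse > 50 * base


class TestChannelConventions:
    def test_channel_ratio_brackets_near_equality(self, default_optics):
        e = channel_hwhm_um(default_optics, Channel.E)
        d5 = channel_hwhm_um(default_optics, Channel.D5)
        assert 0.95 <= e / d5 <= 1.10

    def test_excitation_convention_splits_channels_more(self, default_optics):
        e = channel_hwhm_um(default_optics, Channel.E, convention="excitation")
        d5 = channel_hwhm_um(default_optics, Channel.D5, convention="excitation")
        assert e > d5  # shorter excitation wavelength -> weaker normalized grid
        assert 0.95 <= e / d5 <= 1.10

    def test_unknown_convention_rejected(self, default_optics):
        with pytest.raises(ValueError):
            channel_hwhm_um(default_optics, Channel.E, convention="banana")

    def test_emission_filter_preset_changes_result_slightly(self, default_optics):
        from pseudohe.core import ChannelOptics

        filt = OpticsConfig(channels={
            Channel.D5: ChannelOptics(630.0, (665.0, 780.0), lambda_em_center_nm=730.0),
            Channel.E: ChannelOptics(470.0, (530.0, 620.0), lambda_em_center_nm=595.0),
        })
        default = channel_hwhm_um(default_optics, Channel.E)
        preset = channel_hwhm_um(filt, Channel.E)
        assert preset != default
        assert preset == pytest.approx(default, rel=0.1)
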