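"""Closed-form optical-sectioning theory for grid-projection SIM.

A line grid of spatial frequency ``f`` projected through an objective of
numerical aperture NA loses modulation contrast with defocus; the sectioned
image therefore rejects out-of-focus planes.  The attenuation of the grid
modulation with defocus follows the classic grid-projection result

    attenuation(z) = | 2 J1(u·T) / (u·T) |,    T = ν (1 − ν/2),

where ``ν = f·λ/NA`` is the grid frequency normalized to the incoherent
cutoff (ν ∈ (0, 2), usable sectioning for ν < 1), J1 is the first-order
Bessel function, and ``u`` is the normalized defocus coordinate

    u = c_u · k · z · n · sin²(α/2),    k = 2π/λ,  sin α = NA/n.

The half-width at half-maximum (HWHM) of this curve is the effective
optical-section thickness — the computational analog of the microtome
section.

Wavelength convention and the defocus constant
----------------------------------------------
For a fluorescence system the excitation wavelength forms the grid while the
emission wavelength images it, and published descriptions of this instrument
class do not pin down which wavelength enters each factor nor the exact
defocus normalization.  Two conventions are provided:

``"emission"`` (default)
    The emission-band center enters both ν and u.  Because λ then cancels to
    first order (``u·T ≈ c_u·2π·z·sin²(α/2)·f/NA``), the two channels of a
    dual-color system have nearly identical section thicknesses — the
    behavior reported for the reference instrument (18.8 μm vs 18.7 μm at
    f = 17.1 cycles/mm, 10X/0.45 NA).
``"excitation"``
    The excitation (LED) wavelength enters ν, the emission center enters u.

The defocus constant ``c_u`` is treated as an instrument constant calibrated
once, per convention, against the two published section thicknesses above;
it is held fixed thereafter (see docs/methods.md for the calibration
account).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1

from .core import Channel, OpticsConfig

__all__ = [
    "AxialResponseCurve",
    "normalized_frequency",
    "axial_response",
    "hwhm",
    "channel_axial_response",
    "channel_hwhm_um",
    "DEFOCUS_CONSTANT",
]

#: Argument at which |2·J1(x)/x| first falls to 1/2 (root of 2 J1(x)/x = 1/2).
X_HALF = 2.2150893677242330

#: First zero of J1 (end of the attenuation curve's first lobe).
X_FIRST_ZERO = 3.8317059702075125

#: Calibrated defocus-coordinate constants per wavelength convention
#: (fit to the published 18.8 / 18.7 μm channel HWHMs; see module docstring).
DEFOCUS_CONSTANT = {
    "emission": 9.3665,
    "excitation": 11.0883,
}

_CONVENTIONS = tuple(DEFOCUS_CONSTANT)


def normalized_frequency(f_cycles_per_mm: float, lambda_nm: float, na: float) -> float:
    """Normalized grid frequency ``ν = f · λ / NA`` (dimensionless).

    Raises if ν ≥ 1: the grid would lie beyond the usable passband and the
    sectioning theory below does not apply.
    """
    if f_cycles_per_mm <= 0 or lambda_nm <= 0 or na <= 0:
        raise ValueError("grid frequency, wavelength and NA must all be positive")
    nu = f_cycles_per_mm * 1e3 * lambda_nm * 1e-9 / na
    if nu >= 1.0:
        raise ValueError(
            f"normalized frequency {nu:.4f} >= 1: grid beyond the usable cutoff"
        )
    return nu


def _grating_term(nu: float) -> float:
    if not (0.0 < nu < 1.0):
        raise ValueError(f"normalized frequency must lie in (0, 1), got {nu}")
    return nu * (1.0 - nu / 2.0)


def _jinc_abs(x: np.ndarray) -> np.ndarray:
    """|2·J1(x)/x| with the x → 0 limit of 1."""
    x = np.asarray(x, dtype=np.float64)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = np.abs(2.0 * j1(x[nz]) / x[nz])
    return out


@dataclass
class AxialResponseCurve:
    """Sampled modulation attenuation versus defocus for one configuration."""

    nu: float
    defocus_um: np.ndarray
    attenuation: np.ndarray
    #: u per micron of defocus (the sampled curve's internal normalization);
    #: 0 for purely tabulated curves.
    u_per_um: float = 0.0
    #: Analytic evaluator attenuation(z_um), when the curve has one.
    evaluate: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        self.defocus_um = np.asarray(self.defocus_um, dtype=np.float64)
        self.attenuation = np.asarray(self.attenuation, dtype=np.float64)
        if self.defocus_um.shape != self.attenuation.shape or self.defocus_um.ndim != 1:
            raise ValueError("defocus_um and attenuation must be matching 1-D arrays")

    @property
    def hwhm_um(self) -> float:
        return hwhm(self)


def axial_response(
    nu: float,
    lambda_eff_nm: float,
    na: float,
    n_immersion: float = 1.0,
    z_grid_um: np.ndarray | None = None,
    c_u: float = DEFOCUS_CONSTANT["emission"],
) -> AxialResponseCurve:
    """Theoretical axial attenuation curve of the grid modulation.

    Parameters
    ----------
    nu
        Normalized grid frequency, in (0, 1).
    lambda_eff_nm
        Wavelength entering the defocus coordinate, in nm.
    na, n_immersion
        Objective numerical aperture and immersion refractive index.
    z_grid_um
        Defocus positions to sample (μm).  Defaults to a symmetric grid
        spanning the first lobe with margin.
    c_u
        Defocus-coordinate constant (see module docstring).

    The returned curve is normalized to 1 at z = 0 by construction and is
    even in z.
    """
    T = _grating_term(nu)
    if not (0 < na <= n_immersion):
        raise ValueError("need 0 < NA <= immersion index")
    sin_alpha = na / n_immersion
    k_per_um = 2.0 * math.pi / (lambda_eff_nm * 1e-3)  # rad/μm
    s2 = math.sin(0.5 * math.asin(sin_alpha)) ** 2
    u_per_um = c_u * k_per_um * n_immersion * s2

    def evaluate(z_um: np.ndarray) -> np.ndarray:
        return _jinc_abs(u_per_um * np.asarray(z_um, dtype=np.float64) * T)

    if z_grid_um is None:
        z_lobe = X_FIRST_ZERO / (u_per_um * T)
        z_grid_um = np.linspace(-1.5 * z_lobe, 1.5 * z_lobe, 1201)
    z_grid_um = np.asarray(z_grid_um, dtype=np.float64)
    return AxialResponseCurve(
        nu=nu,
        defocus_um=z_grid_um,
        attenuation=evaluate(z_grid_um),
        u_per_um=u_per_um,
        evaluate=evaluate,
    )


def hwhm(curve: AxialResponseCurve, tol_um: float = 1e-3) -> float:
    """Half-width at half-maximum of the axial response, in μm.

    Solves ``attenuation(z) = 1/2`` on the first lobe by bisection.  Curves
    carrying an analytic evaluator are solved exactly (to ``tol_um``);
    purely tabulated curves are solved on their linear interpolant.
    """
    if curve.evaluate is not None and curve.u_per_um > 0:
        z_half_guess = X_HALF / (curve.u_per_um * _grating_term(curve.nu))
        f = lambda z: float(curve.evaluate(np.asarray([z]))[0]) - 0.5  # noqa: E731
        lo, hi = 0.0, z_half_guess
        # widen until bracketed (guess is exact for the analytic form, but
        # stay robust to rescaled evaluators)
        for _ in range(60):
            if f(hi) < 0:
                break
            hi *= 1.5
        else:
            raise ValueError("axial response never falls to 1/2 on the first lobe")
        return float(brentq(f, lo, hi, xtol=tol_um))

    z = curve.defocus_um
    att = curve.attenuation
    pos = z >= 0
    if not pos.any():
        raise ValueError("curve has no non-negative defocus samples")
    z, att = z[pos], att[pos]
    order = np.argsort(z)
    z, att = z[order], att[order]
    below = np.nonzero(att < 0.5)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError("sampled curve does not cross 1/2 within its range")
    i = below[0]
    z0, z1, a0, a1 = z[i - 1], z[i], att[i - 1], att[i]
    # linear interpolation between the bracketing samples
    return float(z0 + (a0 - 0.5) / (a0 - a1) * (z1 - z0))


def _channel_wavelengths_nm(
    optics: OpticsConfig, channel: Channel, convention: str
) -> tuple[float, float]:
    """(wavelength entering ν, wavelength entering u), in nm."""
    if convention not in _CONVENTIONS:
        raise ValueError(
            f"unknown wavelength convention {convention!r}; choose from {_CONVENTIONS}"
        )
    ch = optics.channel_optics(channel)
    lambda_u = ch.em_center_nm
    lambda_nu = ch.em_center_nm if convention == "emission" else ch.lambda_ex_nm
    return lambda_nu, lambda_u


def channel_axial_response(
    optics: OpticsConfig,
    channel: Channel,
    convention: str = "emission",
    z_grid_um: np.ndarray | None = None,
    c_u: float | None = None,
) -> AxialResponseCurve:
    """Axial response of one fluorescence channel of a configured system."""
    lambda_nu, lambda_u = _channel_wavelengths_nm(optics, channel, convention)
    nu = normalized_frequency(
        optics.grid_freq_cycles_per_mm, lambda_nu, optics.numerical_aperture
    )
    if c_u is None:
        c_u = DEFOCUS_CONSTANT[convention]
    return axial_response(
        nu,
        lambda_u,
        optics.numerical_aperture,
        optics.immersion_index,
        z_grid_um=z_grid_um,
        c_u=c_u,
    )


def channel_hwhm_um(
    optics: OpticsConfig,
    channel: Channel,
    convention: str = "emission",
    c_u: float | None = None,
) -> float:
    """Theoretical optical-section HWHM of one channel, in μm."""
    return hwhm(channel_axial_response(optics, channel, convention, c_u=c_u))
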