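"""Flat-field correction and nonlinear channel compression / balancing.

Each raw frame is divided by a calibration image of a uniform fluorescent
sample, removing the illumination profile.  After mosaicking, each channel
mosaic ``I`` is compressed as ``scale · I**gamma`` (gamma < 1 lifts dim
structure of the large-dynamic-range fluorescence images) and the two
channels are balanced so their foreground means match.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .core import (
    SCALE_A_RANGE,
    SCALE_B_RANGE,
    ChannelImage,
    FlatFieldCalibration,
    RenderParams,
)

__all__ = [
    "flatfield_correct",
    "compress_channel",
    "estimate_balance",
    "BALANCE_TARGET_LEVEL",
]

#: Common foreground-mean level both channels are scaled to.  Arbitrary but
#: fixed: mid-scale leaves headroom for the compressed bright tail.
BALANCE_TARGET_LEVEL = 0.5

#: Percentile used for the headroom constraint in estimate_balance.
_HEADROOM_PERCENTILE = 99.9


def flatfield_correct(frame: np.ndarray, calibration: FlatFieldCalibration) -> np.ndarray:
    """Divide a frame by the prepared calibration image, pixelwise.

    A frame identical to the calibration maps to an all-ones grid; the
    calibration is strictly positive by construction (see
    :meth:`FlatFieldCalibration.from_raw`).
    """
    frame = np.asarray(frame, dtype=np.float64)
    ref = calibration.reference
    if frame.shape != ref.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match calibration shape {ref.shape}"
        )
    return frame / ref


def _compress(pixels: np.ndarray, gamma: float, scale: float) -> np.ndarray:
    if not gamma > 0 or gamma > 1:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return np.clip(scale * np.power(pixels, gamma), 0.0, 1.0)


def compress_channel(image: ChannelImage, gamma: float, scale: float) -> ChannelImage:
    """Apply ``scale · I**gamma`` and clip to [0, 1].

    Clipping (rather than renormalizing) keeps the downstream RGB mapping's
    assumption of stain signals ≤ 1 while preserving the color of
    unsaturated pixels.
    """
    return ChannelImage(
        pixels=_compress(image.pixels, gamma, scale),
        channel=image.channel,
        pixel_size_um=image.pixel_size_um,
    )


def _foreground_mask(pixels: np.ndarray) -> np.ndarray:
    """Tissue foreground: pixels above the Otsu threshold.

    Degenerate images (constant, or Otsu separating nothing) fall back to
    all positive pixels; an all-zero channel is an error upstream.
    """
    finite = pixels[np.isfinite(pixels)]
    if finite.size and finite.max() > finite.min():
        mask = pixels > threshold_otsu(pixels)
        if mask.any():
            return mask
    return pixels > 0


def estimate_balance(
    d5: ChannelImage, e: ChannelImage, params: RenderParams | None = None
) -> tuple[float, float]:
    """Estimate the channel-balance coefficients (A, B).

    Inputs are the gamma-compressed (scale 1) channel mosaics.  Each
    coefficient scales its channel's foreground (Otsu) mean to the common
    target level, subject to the 99.9th percentile of the scaled channel not
    exceeding 1, then is clamped to the published operating range
    (A in [0.8, 3], B in [1.5, 5]).  Callers wanting specific values simply
    pass them to :func:`compress_channel` instead.
    """
    del params  # reserved for future per-run options; estimation uses fixed rules

    coeffs = []
    for image, clamp in ((d5, SCALE_A_RANGE), (e, SCALE_B_RANGE)):
        pixels = image.pixels
        if not np.any(pixels > 0):
            raise ValueError(
                f"channel {image.channel} is all-zero; cannot balance an empty foreground"
            )
        mask = _foreground_mask(pixels)
        mean_fg = float(pixels[mask].mean())
        coef = BALANCE_TARGET_LEVEL / mean_fg
        p_hi = float(np.percentile(pixels, _HEADROOM_PERCENTILE))
        if p_hi > 0:
            coef = min(coef, 1.0 / p_hi)
        coeffs.append(float(np.clip(coef, *clamp)))
    return coeffs[0], coeffs[1]
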