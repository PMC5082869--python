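"""Optical-section reconstruction from three phase-shifted grid images.

A line grid projected onto the sample modulates only the in-focus layer;
out-of-focus planes see a nearly uniform illumination.  With three frames at
grid phases 0, 2π/3 and 4π/3, the root-mean-square of the pairwise frame
differences recovers the local modulation amplitude — the optically sectioned
image — while the phase average reproduces the ordinary widefield image.

For ``I_n = I0 + m·cos(φ + θ_n)`` the pairwise squared differences sum to
``(9/2)·m²`` regardless of the absolute phase φ, so the demodulator is scaled
by √2/3 to return exactly ``m`` (unit gain; any overall constant would simply
be absorbed by the downstream channel balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AcquisitionMode, Channel, ChannelImage, RawFrameSet, normalize_16bit

__all__ = ["SectionedImage", "rms_demodulate", "widefield_passthrough"]

_RMS_GAIN = math.sqrt(2.0) / 3.0


@dataclass
class SectionedImage:
    """Demodulated (sectioned) amplitude plus the companion widefield image."""

    sectioned: np.ndarray  # non-negative modulation amplitude
    widefield: np.ndarray  # pixelwise mean of the three phase frames


def rms_demodulate(frames) -> SectionedImage:
    """Demodulate three phase-shifted frames into a sectioned image.

    Parameters
    ----------
    frames
        Sequence of exactly three equal-shape real-valued grids, acquired at
        grid phases 0, 2π/3 and 4π/3 (in any consistent order).

    Returns
    -------
    SectionedImage
        ``sectioned = (√2/3)·√[(I1−I2)² + (I2−I3)² + (I3−I1)²]`` and
        ``widefield = (I1+I2+I3)/3``, both pixelwise.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) != 3:
        raise ValueError(f"RMS demodulation needs exactly 3 phase frames, got {len(frames)}")
    i1, i2, i3 = frames
    if not (i1.shape == i2.shape == i3.shape):
        raise ValueError(
            f"phase frames must share shape, got {[f.shape for f in frames]}"
        )
    sectioned = _RMS_GAIN * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    widefield = (i1 + i2 + i3) / 3.0
    return SectionedImage(sectioned=sectioned, widefield=widefield)


def demodulate_frameset(frameset: RawFrameSet) -> SectionedImage:
    """Normalize a SIM frame set to [0, 1] and demodulate it."""
    if frameset.mode is not AcquisitionMode.SIM:
        raise ValueError("demodulate_frameset requires a SIM-mode frame set")
    return rms_demodulate([normalize_16bit(f) for f in frameset.frames])


def widefield_passthrough(
    frameset: RawFrameSet, pixel_size_um: float = 0.635
) -> ChannelImage:
    """Pass a single widefield frame through as a normalized channel image.

    The non-SIM path: the frame is scaled to [0, 1] and otherwise untouched.
    """
    if frameset.mode is not AcquisitionMode.WIDEFIELD:
        raise ValueError(
            "widefield_passthrough requires a WIDEFIELD frame set; "
            "SIM sets go through rms_demodulate"
        )
    pixels = normalize_16bit(frameset.frames[0])
    return ChannelImage(pixels=pixels, channel=Channel(frameset.channel),
                        pixel_size_um=pixel_size_um)
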