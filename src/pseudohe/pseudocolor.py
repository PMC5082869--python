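"""Virtual-H&E RGB rendering of the preprocessed channel mosaics.

Each stain subtracts its complementary color from white, the fluorescence
analog of brightfield absorption: with unit colors ``c`` (the RGB of a
saturated pure stain), every plane is ``1 − D5·(1 − c_D5) − E·(1 − c_E)``.
Zero stain renders paper-white; a saturated single stain renders exactly its
unit color (blue-purple nuclei for DRAQ5-as-hematoxylin, pink for eosin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import FULL_SCALE_16BIT, RenderParams

__all__ = [
    "PseudoHEImage",
    "map_rgb",
    "green_magenta_composite",
    "write_rgb_tiff",
    "write_png_preview",
]


@dataclass
class PseudoHEImage:
    """An RGB rendering with all components in [0, 1] (H, W, 3)."""

    rgb: np.ndarray

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError(f"rgb must have shape (H, W, 3), got {self.rgb.shape}")
        if not np.all(np.isfinite(self.rgb)):
            raise ValueError("rgb contains non-finite values")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb components must lie in [0, 1]")

    def to_uint16(self) -> np.ndarray:
        """Jointly rescale [0, 1] → [0, 65535] (hue-preserving) for export."""
        return np.round(self.rgb * FULL_SCALE_16BIT).astype(np.uint16)

    def to_uint8(self) -> np.ndarray:
        return np.round(self.rgb * 255).astype(np.uint8)


def map_rgb(
    d5: np.ndarray, e: np.ndarray, params: RenderParams | None = None
) -> PseudoHEImage:
    """Map compressed/balanced stain mosaics to a virtual-H&E RGB image.

    Each plane is ``1 − D5·(1 − c_D5) − E·(1 − c_E)`` with the per-plane
    unit-color coefficients, then clipped to [0, 1].  Clipping (not
    renormalization) preserves single-stain colors exactly; only saturated
    double-stained pixels can drive a plane negative.
    """
    if params is None:
        params = RenderParams()
    d5 = np.asarray(d5, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if d5.shape != e.shape:
        raise ValueError(f"channel shapes differ: {d5.shape} vs {e.shape}")
    for name, coeffs in (("d5_rgb", params.d5_rgb), ("e_rgb", params.e_rgb)):
        if any(not (0.0 <= c <= 1.0) for c in coeffs):
            raise ValueError(f"{name} coefficients must lie in [0, 1], got {coeffs}")
    planes = [
        1.0 - d5 * (1.0 - cd) - e * (1.0 - ce)
        for cd, ce in zip(params.d5_rgb, params.e_rgb)
    ]
    rgb = np.clip(np.stack(planes, axis=-1), 0.0, 1.0)
    return PseudoHEImage(rgb=rgb)


def green_magenta_composite(d5: np.ndarray, e: np.ndarray) -> PseudoHEImage:
    """Fluorescence-style overlay: DRAQ5 in magenta, eosin in green."""
    d5 = np.clip(np.asarray(d5, dtype=np.float64), 0.0, 1.0)
    e = np.clip(np.asarray(e, dtype=np.float64), 0.0, 1.0)
    if d5.shape != e.shape:
        raise ValueError(f"channel shapes differ: {d5.shape} vs {e.shape}")
    return PseudoHEImage(rgb=np.stack([d5, e, d5], axis=-1))


def write_rgb_tiff(image: PseudoHEImage, path: str | Path) -> Path:
    """Write the composite as a 16-bit-per-channel RGB TIFF."""
    path = Path(path)
    tifffile.imwrite(path, image.to_uint16(), photometric="rgb")
    return path


def write_png_preview(image: PseudoHEImage, path: str | Path) -> Path:
    """Write an 8-bit PNG preview of the composite."""
    path = Path(path)
    iio.imwrite(path, image.to_uint8())
    return path
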