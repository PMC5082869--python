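"""Shared data model for the two-channel virtual-H&E pipeline.

The instrument acquires two fluorescence channels per field of view: DRAQ5
(far-red nuclear stain, the hematoxylin analog) and eosin Y (cytoplasmic /
stromal counterstain).  In structured-illumination (SIM) mode each field is
recorded as three phase-shifted frames of a projected line grid; in widefield
mode a single frame is recorded.  All downstream math runs on double-precision
arrays scaled to [0, 1] from the camera's 16-bit output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "FULL_SCALE_16BIT",
    "SIM_PHASES_RAD",
    "Channel",
    "AcquisitionMode",
    "ChannelImage",
    "RawFrameSet",
    "FlatFieldCalibration",
    "RenderParams",
    "ChannelOptics",
    "OpticsConfig",
    "MosaicLayout",
    "normalize_16bit",
]

#: Full scale of the 16-bit camera output; the fixed normalization divisor.
#: Dividing by the global full scale (not a per-image maximum) preserves
#: radiometry between frames, which mosaicking relies on.
FULL_SCALE_16BIT = 65535

#: The three equally spaced grid phases assumed by the RMS demodulator.
SIM_PHASES_RAD = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


class Channel(str, Enum):
    """Fluorescence channel identity."""

    D5 = "d5"  # DRAQ5, nuclear
    E = "e"  # eosin, cytoplasmic/stromal

    def __str__(self) -> str:  # nicer file names / messages
        return self.value


class AcquisitionMode(str, Enum):
    WIDEFIELD = "widefield"
    SIM = "sim"

    def __str__(self) -> str:
        return self.value


def normalize_16bit(frame: np.ndarray) -> np.ndarray:
    """Convert an unsigned-integer camera frame to float64 in [0, 1].

    The divisor is the fixed 16-bit full scale (65535), never a per-image
    statistic, so identical photon counts in different frames map to
    identical values.

    Parameters
    ----------
    frame
        2-D array with an unsigned integer dtype of at most 16 bits.

    Returns
    -------
    numpy.ndarray
        ``frame / 65535`` as float64.
    """
    frame = np.asarray(frame)
    if frame.dtype.kind != "u":
        raise TypeError(
            f"expected an unsigned integer frame, got dtype {frame.dtype}"
        )
    if frame.dtype.itemsize > 2:
        raise TypeError(
            f"frames deeper than 16 bits are not supported (dtype {frame.dtype})"
        )
    return frame.astype(np.float64) / FULL_SCALE_16BIT


@dataclass
class ChannelImage:
    """A [0, 1]-scaled grayscale image tagged with its channel identity."""

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float = 0.635  # 1.3 mm field / 2048 px

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0 + 1e-12:
            raise ValueError(f"pixels outside [0, 1]: range [{lo}, {hi}]")
        self.channel = Channel(self.channel)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class RawFrameSet:
    """The raw 16-bit frames of one channel at one stage position.

    SIM mode carries exactly three phase-shifted frames (phases 0, 2π/3,
    4π/3); widefield mode carries exactly one frame.
    """

    frames: tuple[np.ndarray, ...]
    channel: Channel
    mode: AcquisitionMode
    phases_rad: tuple[float, ...] = SIM_PHASES_RAD
    grid_position: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.mode = AcquisitionMode(self.mode)
        self.frames = tuple(np.asarray(f) for f in self.frames)
        for f in self.frames:
            if f.dtype.kind != "u" or f.dtype.itemsize > 2:
                raise TypeError(f"frames must be unsigned 16-bit, got {f.dtype}")
            if f.shape != self.frames[0].shape:
                raise ValueError("all frames in a set must share dimensions")
        if self.mode is AcquisitionMode.SIM:
            if len(self.frames) != 3:
                raise ValueError(
                    f"SIM frame sets hold exactly 3 phase frames, got {len(self.frames)}"
                )
            self.phases_rad = tuple(float(p) for p in self.phases_rad)
            if len(self.phases_rad) != 3 or not np.allclose(
                self.phases_rad, SIM_PHASES_RAD, atol=1e-9
            ):
                raise ValueError(
                    "SIM phases must be {0, 2pi/3, 4pi/3}; got "
                    f"{self.phases_rad}"
                )
        else:
            if len(self.frames) != 1:
                raise ValueError(
                    f"widefield frame sets hold exactly 1 frame, got {len(self.frames)}"
                )
            self.phases_rad = (0.0,)
        r, c = self.grid_position
        if r < 0 or c < 0:
            raise ValueError("grid_position indices must be non-negative")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape  # type: ignore[return-value]


@dataclass
class FlatFieldCalibration:
    """Per-channel reference image of a uniform fluorescent sample.

    ``reference`` is the *prepared* calibration: float64, floor-clamped so it
    is strictly positive everywhere (dead pixels would otherwise blow up the
    flat-field division).
    """

    reference: np.ndarray
    channel: Channel

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.channel = Channel(self.channel)
        if self.reference.ndim != 2:
            raise ValueError("calibration must be a 2-D image")
        if not np.all(np.isfinite(self.reference)) or np.any(self.reference <= 0):
            raise ValueError(
                "prepared calibration must be strictly positive and finite; "
                "use FlatFieldCalibration.from_raw to floor-clamp a raw image"
            )

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        channel: Channel,
        floor_percentile: float = 1.0,
    ) -> "FlatFieldCalibration":
        """Prepare a calibration from a raw 16-bit or float image.

        Integer input is first scaled to [0, 1].  The image is then clamped
        from below so a few dead (zero) pixels cannot produce division
        blow-ups.  The floor is the ``floor_percentile`` of the positive
        values, capped at half the median so a smooth illumination falloff
        (whose dim corners are real signal) is never distorted.
        """
        raw = np.asarray(raw)
        if raw.dtype.kind == "u":
            prepared = normalize_16bit(raw)
        elif raw.dtype.kind == "f":
            prepared = raw.astype(np.float64)
        else:
            raise TypeError(f"calibration dtype must be unsigned int or float, got {raw.dtype}")
        if not np.all(np.isfinite(prepared)):
            raise ValueError("calibration contains non-finite values")
        positive = prepared[prepared > 0]
        if positive.size == 0:
            raise ValueError("calibration image has no positive pixels")
        floor = min(
            float(np.percentile(positive, floor_percentile)),
            0.5 * float(np.median(positive)),
        )
        return cls(np.maximum(prepared, floor), channel)


#: Eqs-of-the-method RGB unit colors: the rendered color of a saturated
#: pure-stain pixel.  DRAQ5 plays hematoxylin (blue-purple), eosin stays pink.
DEFAULT_D5_RGB = (0.24, 0.21, 0.62)
DEFAULT_E_RGB = (0.88, 0.27, 0.66)

#: Ranges for the channel-balance scale factors reported for the instrument.
SCALE_A_RANGE = (0.8, 3.0)
SCALE_B_RANGE = (1.5, 5.0)
#: Gamma compression exponents stay within this published operating range.
GAMMA_RANGE = (0.65, 1.0)


@dataclass
class RenderParams:
    """Gamma compression, channel balance, and RGB mapping coefficients.

    ``gamma_d5``/``gamma_e`` compress the large dynamic range of each channel
    (values below 1 brighten dim structure); ``scale_a``/``scale_b`` balance
    the mean intensities of the two channels; the two RGB triples set the
    rendered color of each pure stain.
    """

    gamma_d5: float = 0.85
    gamma_e: float = 0.75
    scale_a: float = 1.5
    scale_b: float = 2.5
    d5_rgb: tuple[float, float, float] = DEFAULT_D5_RGB
    e_rgb: tuple[float, float, float] = DEFAULT_E_RGB

    def __post_init__(self) -> None:
        lo, hi = GAMMA_RANGE
        for name, g in (("gamma_d5", self.gamma_d5), ("gamma_e", self.gamma_e)):
            if not (lo <= g <= hi):
                raise ValueError(f"{name}={g} outside the operating range [{lo}, {hi}]")
        if not (SCALE_A_RANGE[0] <= self.scale_a <= SCALE_A_RANGE[1]):
            raise ValueError(
                f"scale_a={self.scale_a} outside {list(SCALE_A_RANGE)}"
            )
        if not (SCALE_B_RANGE[0] <= self.scale_b <= SCALE_B_RANGE[1]):
            raise ValueError(
                f"scale_b={self.scale_b} outside {list(SCALE_B_RANGE)}"
            )
        for name, rgb in (("d5_rgb", self.d5_rgb), ("e_rgb", self.e_rgb)):
            rgb = tuple(float(c) for c in rgb)
            if len(rgb) != 3 or any(not (0.0 <= c <= 1.0) for c in rgb):
                raise ValueError(f"{name} must be three coefficients in [0, 1], got {rgb}")
            setattr(self, name, rgb)


@dataclass(frozen=True)
class ChannelOptics:
    """Excitation/emission wavelengths of one fluorescence channel."""

    lambda_ex_nm: float
    lambda_em_band_nm: tuple[float, float]
    #: Override for the emission center; defaults to the arithmetic band
    #: center.  Set it to the emission-filter center to use that preset.
    lambda_em_center_nm: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.lambda_em_band_nm
        if not (0 < self.lambda_ex_nm) or not (0 < lo < hi):
            raise ValueError("wavelengths must be positive and band ordered (min, max)")

    @property
    def em_center_nm(self) -> float:
        if self.lambda_em_center_nm is not None:
            return float(self.lambda_em_center_nm)
        lo, hi = self.lambda_em_band_nm
        return 0.5 * (lo + hi)


# Instrument defaults: 630 nm LED for DRAQ5 (emission collected 665-780 nm),
# 470 nm LED for eosin (emission collected 530-620 nm).
_DEFAULT_CHANNEL_OPTICS = {
    Channel.D5: ChannelOptics(630.0, (665.0, 780.0)),
    Channel.E: ChannelOptics(470.0, (530.0, 620.0)),
}


@dataclass(frozen=True)
class OpticsConfig:
    """Grid frequency, objective, and per-channel wavelengths of the system."""

    grid_freq_cycles_per_mm: float = 17.1
    numerical_aperture: float = 0.45
    immersion_index: float = 1.0
    magnification: float = 10.0
    channels: dict[Channel, ChannelOptics] = field(
        default_factory=lambda: dict(_DEFAULT_CHANNEL_OPTICS)
    )

    def __post_init__(self) -> None:
        if not self.grid_freq_cycles_per_mm > 0:
            raise ValueError("grid frequency must be positive")
        if not (0 < self.numerical_aperture <= 1.5):
            raise ValueError("numerical aperture must lie in (0, 1.5]")
        if self.immersion_index < 1.0:
            raise ValueError("immersion index must be >= 1")
        if self.numerical_aperture / self.immersion_index > 1.0:
            raise ValueError("NA must not exceed the immersion index")
        object.__setattr__(
            self,
            "channels",
            {Channel(k): v for k, v in self.channels.items()},
        )

    def channel_optics(self, channel: Channel) -> ChannelOptics:
        return self.channels[Channel(channel)]


@dataclass(frozen=True)
class MosaicLayout:
    """Stage-position grid: row-major tiles, origin top-left, 0-based."""

    n_rows: int
    n_cols: int
    frame_shape: tuple[int, int]
    overlap_px: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout must have at least one row and one column")
        h, w = self.frame_shape
        ovr, ovc = self.overlap_px
        if h < 1 or w < 1:
            raise ValueError("frame_shape must be positive")
        if ovr < 0 or ovc < 0:
            raise ValueError("overlap must be non-negative")
        if ovr >= h or ovc >= w:
            raise ValueError("overlap must be strictly smaller than the frame dimension")

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        h, w = self.frame_shape
        ovr, ovc = self.overlap_px
        return (
            self.n_rows * h - (self.n_rows - 1) * ovr,
            self.n_cols * w - (self.n_cols - 1) * ovc,
        )

    def positions(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def origin_of(self, position: tuple[int, int]) -> tuple[int, int]:
        """Top-left pixel of a tile in mosaic coordinates."""
        r, c = position
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError(f"position {position} outside the {self.n_rows}x{self.n_cols} layout")
        h, w = self.frame_shape
        ovr, ovc = self.overlap_px
        return r * (h - ovr), c * (w - ovc)
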