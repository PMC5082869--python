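"""On-disk layout of an acquisition and TIFF I/O helpers.

An acquisition is one directory holding 16-bit grayscale TIFF frames named

    {channel}_pos{row}_{col}_phase{k}.tif      (k = 0,1,2 in SIM mode,
                                                k = 0 only in widefield)

one flat-field calibration per channel, ``flatfield_{channel}.tif``, and a
YAML run configuration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .core import AcquisitionMode, Channel, MosaicLayout, RawFrameSet

__all__ = [
    "frame_filename",
    "calibration_filename",
    "read_frame",
    "write_frame",
    "read_frameset",
    "write_acquisition_frames",
]


def frame_filename(channel: Channel, row: int, col: int, phase_index: int) -> str:
    return f"{Channel(channel)}_pos{row}_{col}_phase{phase_index}.tif"


def calibration_filename(channel: Channel) -> str:
    return f"flatfield_{Channel(channel)}.tif"


def read_frame(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"frame file not found: {path}")
    frame = tifffile.imread(path)
    if frame.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, got shape {frame.shape}")
    return frame


def write_frame(path: str | Path, frame: np.ndarray) -> Path:
    path = Path(path)
    frame = np.asarray(frame)
    if frame.dtype != np.uint16:
        raise TypeError(f"frames are written as 16-bit grayscale, got {frame.dtype}")
    tifffile.imwrite(path, frame, photometric="minisblack")
    return path


def read_frameset(
    directory: str | Path,
    channel: Channel,
    position: tuple[int, int],
    mode: AcquisitionMode,
) -> RawFrameSet:
    """Read the 1 (widefield) or 3 (SIM) frames of one channel/position."""
    directory = Path(directory)
    n_phases = 3 if AcquisitionMode(mode) is AcquisitionMode.SIM else 1
    frames = tuple(
        read_frame(directory / frame_filename(channel, *position, k))
        for k in range(n_phases)
    )
    return RawFrameSet(frames=frames, channel=channel, mode=mode, grid_position=position)


def write_acquisition_frames(
    directory: str | Path,
    framesets: list[RawFrameSet],
    calibrations: dict[Channel, np.ndarray],
    layout: MosaicLayout,
) -> Path:
    """Write framesets and calibrations in the standard directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fs in framesets:
        for k, frame in enumerate(fs.frames):
            write_frame(
                directory / frame_filename(fs.channel, *fs.grid_position, k), frame
            )
    for channel, calib in calibrations.items():
        write_frame(directory / calibration_filename(channel), calib)
    del layout  # recorded by the caller's config file
    return directory
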