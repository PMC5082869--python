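"""Assembly of per-position frames into a single channel mosaic.

Stage positions are taken as exact (motorized-stage tiling), so tiles are
placed at known offsets; where configured overlap exists, the seam is blended
by separable linear feathering whose weights form an exact partition of
unity, so uniform tiles assemble into a perfectly flat mosaic.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .core import MosaicLayout

__all__ = ["assemble"]


def _axis_weights(index: int, n_tiles: int, size: int, overlap: int) -> np.ndarray:
    """1-D feather profile for tile `index` of `n_tiles` along one axis.

    Within an overlap strip the leading tile ramps down as ``1 - a`` while the
    trailing tile ramps up as ``a`` at the same mosaic pixels, with
    ``a = (i + 1/2) / overlap``; the two always sum to exactly 1.
    """
    w = np.ones(size, dtype=np.float64)
    if overlap > 0:
        ramp = (np.arange(overlap, dtype=np.float64) + 0.5) / overlap
        if index > 0:
            w[:overlap] = ramp
        if index < n_tiles - 1:
            w[size - overlap:] = ramp[::-1]
    return w


def assemble(
    frames: Iterable[tuple[tuple[int, int], np.ndarray]],
    layout: MosaicLayout,
) -> np.ndarray:
    """Assemble ``(grid_position, frame)`` pairs into the mosaic.

    Every cell of the layout must be supplied exactly once and all frames
    must match ``layout.frame_shape``.  With zero overlap this is pure block
    placement; with overlap, seams are linearly feathered.
    """
    frames = list(frames)
    h, w = layout.frame_shape
    ovr, ovc = layout.overlap_px

    seen: dict[tuple[int, int], np.ndarray] = {}
    for position, frame in frames:
        position = (int(position[0]), int(position[1]))
        frame = np.asarray(frame, dtype=np.float64)
        if frame.shape != (h, w):
            raise ValueError(
                f"frame at {position} has shape {frame.shape}, layout expects {(h, w)}"
            )
        if position in seen:
            raise ValueError(f"duplicate frame for position {position}")
        layout.origin_of(position)  # validates the index range
        seen[position] = frame
    missing = [p for p in layout.positions() if p not in seen]
    if missing:
        raise ValueError(f"missing frames for positions {missing}")

    out_shape = layout.mosaic_shape
    acc = np.zeros(out_shape, dtype=np.float64)
    weight = np.zeros(out_shape, dtype=np.float64)
    for (r, c), frame in seen.items():
        wy = _axis_weights(r, layout.n_rows, h, ovr)
        wx = _axis_weights(c, layout.n_cols, w, ovc)
        tile_w = np.outer(wy, wx)
        y0, x0 = layout.origin_of((r, c))
        acc[y0 : y0 + h, x0 : x0 + w] += tile_w * frame
        weight[y0 : y0 + h, x0 : x0 + w] += tile_w
    return acc / weight
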