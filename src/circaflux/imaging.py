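"""Image-stack preprocessing and ROI trace extraction.

Mirrors the standard bioluminescence time-lapse workflow: selective-median
removal of cosmic-ray pixels, optional global contrast rescaling, a grid of
non-overlapping square ROIs over the culture-chamber mask, and per-ROI mean
intensity traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageStack, InvalidInputError, TraceSet


def remove_cosmic_rays(stack: ImageStack, radius_px: int = 2,
                       threshold: float = 50.0,
                       bright_only: bool = True) -> ImageStack:
    """Selective median filter: replace only outlier pixels.

    A pixel is replaced by the median of its (2*radius+1)^2 neighborhood
    only when it deviates from that median by more than ``threshold``
    (``bright_only`` restricts to positive deviations, the cosmic-ray
    case); all other pixels pass through unchanged.  Defaults follow the
    ImageJ Remove Outliers convention (radius 2 px, threshold 50, bright).
    """
    if radius_px < 1:
        raise InvalidInputError("radius_px must be >= 1")
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    size = 2 * radius_px + 1
    out = np.array(stack.frames, dtype=float, copy=True)
    for k in range(stack.n_frames):
        frame = out[k]
        med = ndimage.median_filter(frame, size=size, mode="reflect")
        dev = frame - med
        mask = dev > threshold if bright_only else np.abs(dev) > threshold
        frame[mask] = med[mask]
    return ImageStack(out, stack.timestamps_h.copy(), stack.bit_depth)


def rescale_contrast(stack: ImageStack, bit_depth: int | None = None) -> ImageStack:
    """Min-max rescale to the full bit range with one global min/max.

    A single (min, max) across the whole stack preserves relative temporal
    dynamics; per-frame scaling would destroy the amplitude information the
    downstream fits need, so this step is off the quantitative path by
    default.  A constant stack is returned unchanged (no divide-by-zero).
    """
    if stack.n_frames == 0:
        raise InvalidInputError("empty stack")
    depth = bit_depth if bit_depth is not None else stack.bit_depth
    lo = float(stack.frames.min())
    hi = float(stack.frames.max())
    if hi == lo:
        return ImageStack(np.array(stack.frames, dtype=float),
                          stack.timestamps_h.copy(), depth)
    top = float(2 ** depth - 1)
    scaled = (np.asarray(stack.frames, dtype=float) - lo) / (hi - lo) * top
    return ImageStack(scaled, stack.timestamps_h.copy(), depth)


@dataclass
class ROIGrid:
    """Non-overlapping square ROIs anchored at ``origin`` (row, col).

    Pixel coordinates are 0-based and row-major; ROI bounds are half-open
    ``[r0, r1) x [c0, c1)`` intervals.  ``mask`` flags which grid cells are
    included (all by default).
    """

    roi_size_px: int
    origin: tuple[int, int]
    n_rows: int
    n_cols: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_rows, self.n_cols):
            raise InvalidInputError("mask shape must be (n_rows, n_cols)")

    @property
    def n_rois(self) -> int:
        return int(self.mask.sum())

    def bounds(self, i: int, j: int) -> tuple[int, int, int, int]:
        """Half-open pixel bounds (r0, r1, c0, c1) of grid cell (i, j)."""
        s = self.roi_size_px
        r0 = self.origin[0] + i * s
        c0 = self.origin[1] + j * s
        return r0, r0 + s, c0, c0 + s

    def rois(self) -> list[tuple[int, int]]:
        """Included (row, col) grid positions, row-major."""
        return [(i, j) for i in range(self.n_rows) for j in range(self.n_cols)
                if self.mask[i, j]]

    def to_dict(self) -> dict:
        return {"roi_size_px": self.roi_size_px, "origin": list(self.origin),
                "n_rows": self.n_rows, "n_cols": self.n_cols,
                "mask": self.mask.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ROIGrid":
        return cls(d["roi_size_px"], tuple(d["origin"]), d["n_rows"],
                   d["n_cols"], np.asarray(d["mask"], dtype=bool))


def define_roi_grid(frame_shape: tuple[int, int], roi_size_px: int,
                    chamber_mask: np.ndarray | None = None) -> ROIGrid:
    """Lay a grid of non-overlapping ROIs over the chamber region.

    ``chamber_mask`` is a boolean frame-shaped array marking the culture
    chamber (default: whole frame).  The grid is anchored at the mask's
    bounding-box origin; trailing partial ROIs are dropped so every ROI has
    equal area, and an ROI is included only when fully inside the mask.
    """
    if roi_size_px < 1:
        raise InvalidInputError("roi_size_px must be >= 1")
    if chamber_mask is None:
        chamber_mask = np.ones(frame_shape, dtype=bool)
    chamber_mask = np.asarray(chamber_mask, dtype=bool)
    if chamber_mask.shape != tuple(frame_shape):
        raise InvalidInputError("chamber_mask must match frame_shape")
    rows = np.flatnonzero(chamber_mask.any(axis=1))
    cols = np.flatnonzero(chamber_mask.any(axis=0))
    if rows.size == 0:
        raise InvalidInputError("chamber mask is empty")
    r0, c0 = int(rows[0]), int(cols[0])
    height = int(rows[-1]) - r0 + 1
    width = int(cols[-1]) - c0 + 1
    n_rows = height // roi_size_px
    n_cols = width // roi_size_px
    if n_rows < 1 or n_cols < 1:
        raise InvalidInputError("chamber mask smaller than one ROI")
    mask = np.empty((n_rows, n_cols), dtype=bool)
    for i in range(n_rows):
        for j in range(n_cols):
            rr = slice(r0 + i * roi_size_px, r0 + (i + 1) * roi_size_px)
            cc = slice(c0 + j * roi_size_px, c0 + (j + 1) * roi_size_px)
            mask[i, j] = bool(chamber_mask[rr, cc].all())
    if not mask.any():
        raise InvalidInputError("no ROI fits fully inside the chamber mask")
    return ROIGrid(roi_size_px, (r0, c0), n_rows, n_cols, mask)


def extract_traces(stack: ImageStack, grid: ROIGrid,
                   condition: str | None = None) -> TraceSet:
    """Mean ROI intensity per frame; one trace per included grid cell.

    Trace ids encode the grid position as ``r{row}c{col}``.
    """
    h, w = stack.frame_shape
    last_r = grid.origin[0] + grid.n_rows * grid.roi_size_px
    last_c = grid.origin[1] + grid.n_cols * grid.roi_size_px
    if last_r > h or last_c > w:
        raise InvalidInputError("ROI grid extends beyond the frame")
    names, cols = [], []
    frames = np.asarray(stack.frames, dtype=float)
    for i, j in grid.rois():
        rr0, rr1, cc0, cc1 = grid.bounds(i, j)
        cols.append(frames[:, rr0:rr1, cc0:cc1].mean(axis=(1, 2)))
        names.append(f"r{i}c{j}")
    return TraceSet(stack.timestamps_h.copy(), np.column_stack(cols),
                    names, condition)
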