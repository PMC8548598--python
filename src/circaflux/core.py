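"""Shared containers and I/O: luminescence trace sets and image stacks.

Traces are stored as a time-by-trace matrix with a common time grid in
hours; image stacks are time-ordered grayscale frames.  CSV and TIFF are
the on-disk formats (``time_h,<trace_id>,...`` columns for traces,
multi-page grayscale TIFF for stacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass
class TraceSet:
    """Named luminescence traces (a.u.) sharing one time grid (hours).

    Parameters
    ----------
    time_h : array of shape (n_time,)
        Strictly increasing sample times in hours.
    values : array of shape (n_time, n_traces)
        Intensity values, one column per trace.
    names : list of str
        Trace identifiers (ROI positions, chamber or dish labels).
    condition : str, optional
        Experimental condition label (e.g. ``"HL"``).
    """

    time_h: np.ndarray
    values: np.ndarray
    names: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.time_h.ndim != 1:
            raise InvalidInputError("time_h must be 1-D")
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError("time_h must be strictly increasing")
        if self.values.shape[0] != self.time_h.size:
            raise InvalidInputError("values rows must match time grid length")
        self.names = [str(n) for n in self.names]
        if len(self.names) != self.values.shape[1]:
            raise InvalidInputError("one name per trace column required")

    @property
    def n_traces(self) -> int:
        return self.values.shape[1]

    @property
    def dt_h(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.time_h)))

    def trace(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def with_values(self, values: np.ndarray) -> "TraceSet":
        return TraceSet(self.time_h.copy(), np.asarray(values, dtype=float),
                        list(self.names), self.condition)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_h", self.time_h)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, condition: str | None = None) -> "TraceSet":
        df = pd.read_csv(path)
        if "time_h" not in df.columns:
            raise InvalidInputError("trace CSV must have a 'time_h' column")
        names = [c for c in df.columns if c != "time_h"]
        return cls(df["time_h"].to_numpy(), df[names].to_numpy(), names, condition)


@dataclass
class ImageStack:
    """Time-ordered grayscale frames with per-frame timestamps.

    ``frames`` has shape (n_time, n_rows, n_cols); ``timestamps_h`` is
    strictly increasing.  ``bit_depth`` records the nominal acquisition
    depth (frames may be held as float for quantitative work).
    """

    frames: np.ndarray
    timestamps_h: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidInputError("frames must be 3-D (time, rows, cols)")
        if self.timestamps_h.size != self.frames.shape[0]:
            raise InvalidInputError("one timestamp per frame required")
        if self.timestamps_h.size > 1 and np.any(np.diff(self.timestamps_h) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def astype_uint16(self) -> "ImageStack":
        clipped = np.clip(np.rint(self.frames), 0, np.iinfo(np.uint16).max)
        return ImageStack(clipped.astype(np.uint16), self.timestamps_h.copy(), 16)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | Path,
                  timestamps_h: np.ndarray | None = None,
                  dt_h: float = 0.5, t0_h: float = 0.0,
                  bit_depth: int = 16) -> "ImageStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if timestamps_h is None:
            timestamps_h = t0_h + dt_h * np.arange(frames.shape[0])
        return cls(frames, np.asarray(timestamps_h, dtype=float), bit_depth)
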