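"""Time-lapse stack I/O, the two-rate timebase, and maximum-intensity projection.

The canonical in-memory axis order is ``[t][z][y][x]``; readers reorder any
dialect into this order and a missing Z axis is treated as Z=1.  Time is
continuous seconds with t=0 at acquisition start; the irradiation event is
carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "TimeLapseStack",
    "FrameSeries",
    "StackValidationError",
    "read_stack",
    "write_stack",
    "build_timebase",
    "max_project",
]


class StackValidationError(ValueError):
    """Raised when a stack or its metadata violates the container invariants."""


@dataclass
class TimeLapseStack:
    """A T×Z×Y×X fluorescence time-lapse with acquisition geometry.

    Parameters
    ----------
    pixels : ndarray, shape (T, Z, Y, X)
        Camera counts (arbitrary units, within the camera bit range).
    timestamps : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing,
        with t=0 at acquisition start.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    bit_depth : int
        Camera bit depth; intensities must lie in [0, 2**bit_depth - 1].
    irradiation_time_s : float
        Time of the laser irradiation event (point A) in seconds.
    """

    pixels: np.ndarray
    timestamps: np.ndarray
    pixel_size_um: float
    bit_depth: int = 12
    irradiation_time_s: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.pixels.ndim == 3:  # missing Z axis -> Z=1
            self.pixels = self.pixels[:, None, :, :]
        if self.pixels.ndim != 4:
            raise StackValidationError(
                f"expected 3 or 4 axes (T[,Z],Y,X), got {self.pixels.ndim}"
            )
        t = self.pixels.shape[0]
        if self.timestamps.shape != (t,):
            raise StackValidationError(
                f"timestamps length {self.timestamps.shape} does not match T={t}"
            )
        if t > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise StackValidationError("timestamps must be strictly increasing")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise StackValidationError("negative intensities")
        vmax = 2 ** self.bit_depth - 1
        if self.pixels.size and float(self.pixels.max()) > vmax:
            raise StackValidationError(f"intensities exceed {self.bit_depth}-bit range")
        if not (self.timestamps[0] <= self.irradiation_time_s <= self.timestamps[-1]):
            raise StackValidationError(
                "irradiation_time_s outside the acquisition time window"
            )
        if self.pixel_size_um <= 0:
            raise StackValidationError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FrameSeries:
    """A 2-D frame series (T×Y×X) carrying timestamps through every transform."""

    frames: np.ndarray
    timestamps: np.ndarray
    provenance: str = "raw-MIP"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise StackValidationError("FrameSeries expects (T, Y, X)")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise StackValidationError("timestamps length must equal T")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def with_frames(self, frames: np.ndarray, provenance: str) -> "FrameSeries":
        return FrameSeries(frames=frames, timestamps=self.timestamps.copy(), provenance=provenance)


def build_timebase(n_fast: int, fast_dt_s: float, slow_dt_s: float, total_frames: int) -> np.ndarray:
    """Two-rate acquisition timebase: ``n_fast`` fast intervals then slow ones.

    The camera records at a high frame rate (e.g. 1 fps) around the
    irradiation event to resolve the rapid association phase, then drops to a
    slow rate (e.g. 0.2 fps) for the long dissociation phase.  Returns
    timestamps in seconds with ``timestamps[0] = 0``.
    """
    if n_fast > total_frames:
        raise ValueError("n_fast cannot exceed total_frames")
    if fast_dt_s <= 0 or slow_dt_s <= 0:
        raise ValueError("frame intervals must be positive")
    if total_frames < 1:
        raise ValueError("total_frames must be >= 1")
    n_fast_intervals = min(n_fast, total_frames - 1)
    dts = np.concatenate([
        np.full(n_fast_intervals, float(fast_dt_s)),
        np.full(total_frames - 1 - n_fast_intervals, float(slow_dt_s)),
    ])
    return np.concatenate([[0.0], np.cumsum(dts)])


def read_stack(path, metadata: dict) -> TimeLapseStack:
    """Read a TIFF/OME-TIFF stack into a validated :class:`TimeLapseStack`.

    ``metadata`` supplies what the file may not embed: either explicit
    ``timestamps`` or a rate schedule ``(n_fast, fast_dt_s, slow_dt_s)``, plus
    ``pixel_size_um``, ``bit_depth`` and ``irradiation_time_s``.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim not in (3, 4):
        raise StackValidationError(f"stack must have 3 or 4 axes, got {arr.ndim}")
    n_t = arr.shape[0]
    if "timestamps" in metadata and metadata["timestamps"] is not None:
        timestamps = np.asarray(metadata["timestamps"], dtype=float)
    else:
        timestamps = build_timebase(
            int(metadata["n_fast"]),
            float(metadata["fast_dt_s"]),
            float(metadata["slow_dt_s"]),
            n_t,
        )
    return TimeLapseStack(
        pixels=arr,
        timestamps=timestamps,
        pixel_size_um=float(metadata.get("pixel_size_um", 0.22955)),
        bit_depth=int(metadata.get("bit_depth", 12)),
        irradiation_time_s=float(metadata.get("irradiation_time_s", 1.0)),
    )


def write_stack(path, stack: TimeLapseStack) -> None:
    """Write a stack as (T, Z, Y, X) TIFF, preserving integer dtype if present."""
    tifffile.imwrite(str(path), np.asarray(stack.pixels))


def max_project(stack: TimeLapseStack) -> FrameSeries:
    """Per-pixel maximum-intensity projection over Z, timestamps preserved."""
    return FrameSeries(
        frames=stack.pixels.max(axis=1).astype(float),
        timestamps=stack.timestamps.copy(),
        provenance="raw-MIP",
    )
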