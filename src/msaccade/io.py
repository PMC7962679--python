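"""Gaze-data containers, tabular readers/writers and unit conversion.

Conventions used throughout the package:

* timestamps are milliseconds, uniformly spaced at ``1000 / sampling_rate``;
* gaze positions are degrees of visual angle;
* sample intervals are half-open, 0-based ``[onset, offset)``;
* missing pupil (blink) is encoded as NaN in memory and as an empty field
  (or a configurable sentinel such as 0) on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeRecording",
    "ScreenGeometry",
    "pixels_to_degrees",
    "read_gaze_table",
    "write_gaze_table",
]

#: default column names of the native tab-separated gaze format
GAZE_COLUMNS = ("t_ms", "x_l", "y_l", "x_r", "y_r", "pupil_l", "pupil_r")


class GazeFormatError(ValueError):
    """Raised when a gaze table violates the format contract."""


@dataclass
class ScreenGeometry:
    """Monitor geometry needed to convert pixel offsets to visual angle.

    The 57 cm viewing distance is the classic convenience distance at which
    1 cm on screen subtends almost exactly 1 degree.
    """

    viewing_distance_cm: float = 57.0
    pixels_per_cm: float = 38.0
    screen_center_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing_distance_cm must be positive")
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")


def pixels_to_degrees(offset_px: float | np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Convert a pixel offset from screen center to degrees of visual angle.

    ``deg = atan(offset_cm / viewing_distance)``; odd in the offset, so
    symmetric offsets map to equal magnitudes with opposite signs.
    """
    offset_cm = np.asarray(offset_px, dtype=float) / geometry.pixels_per_cm
    return np.degrees(np.arctan2(offset_cm, geometry.viewing_distance_cm))


@dataclass
class GazeRecording:
    """A binocular gaze recording sampled at a fixed rate.

    Attributes
    ----------
    t_ms : array of timestamps in ms, uniform step 1000/sampling_rate.
    x_l, y_l, x_r, y_r : per-eye gaze position in degrees of visual angle.
    pupil_l, pupil_r : pupil area in arbitrary tracker units; NaN = missing.
    sampling_rate : samples per second.
    meta : free-form labels (subject, condition, ...).
    """

    t_ms: np.ndarray
    x_l: np.ndarray
    y_l: np.ndarray
    x_r: np.ndarray
    y_r: np.ndarray
    pupil_l: np.ndarray
    pupil_r: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        for name in ("x_l", "y_l", "x_r", "y_r", "pupil_l", "pupil_r"):
            if len(getattr(self, name)) != n:
                raise GazeFormatError(f"channel {name!r} has length "
                                      f"{len(getattr(self, name))}, expected {n}")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def positions(self, eye: str) -> np.ndarray:
        """Return an (n, 2) array of (x, y) positions for ``'left'``/``'right'``."""
        if eye == "left":
            return np.column_stack([self.x_l, self.y_l])
        if eye == "right":
            return np.column_stack([self.x_r, self.y_r])
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms,
            "x_l": self.x_l, "y_l": self.y_l,
            "x_r": self.x_r, "y_r": self.y_r,
            "pupil_l": self.pupil_l, "pupil_r": self.pupil_r,
        })


def write_gaze_table(recording: GazeRecording, path, float_format: str = "%.6f") -> None:
    """Write a recording as tab-separated text; missing pupil becomes an empty field."""
    recording.to_frame().to_csv(path, sep="\t", index=False,
                                float_format=float_format, na_rep="")


def read_gaze_table(
    path,
    sampling_rate: float | None = None,
    column_map: Mapping[str, str] | None = None,
    pupil_missing_sentinel: float | None = None,
    geometry: ScreenGeometry | None = None,
    position_units: str = "deg",
    timestamp_tolerance_ms: float = 1e-6,
    meta: dict | None = None,
) -> GazeRecording:
    """Read a delimited gaze table into a :class:`GazeRecording`.

    Parameters
    ----------
    sampling_rate
        Samples per second.  If omitted it is inferred from the first
        timestamp step.
    column_map
        Maps the native column names (``t_ms``, ``x_l``, ...) to the names
        used in the file, supporting EyeLink-ASC-derived sample exports.
    pupil_missing_sentinel
        A tracker sentinel (e.g. 0) to be treated as missing pupil, in
        addition to empty fields.
    position_units
        ``"deg"`` (native) or ``"px"``; pixel inputs require ``geometry``
        and are converted through :func:`pixels_to_degrees`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    colmap = dict(zip(GAZE_COLUMNS, GAZE_COLUMNS))
    if column_map:
        colmap.update(column_map)
    missing = [colmap[c] for c in GAZE_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise GazeFormatError(f"missing required column(s): {', '.join(missing)}")

    t = df[colmap["t_ms"]].to_numpy(dtype=float)
    if len(t) < 2:
        raise GazeFormatError("a gaze table needs at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0))
        raise GazeFormatError(
            f"timestamps not strictly increasing at data line {bad + 2}")
    step = steps[0]
    irregular = np.abs(steps - step) > timestamp_tolerance_ms
    if np.any(irregular):
        bad = int(np.argmax(irregular))
        raise GazeFormatError(
            f"non-uniform timestamp step at data line {bad + 2}: "
            f"expected {step} ms, found {steps[bad]} ms")
    inferred_rate = 1000.0 / step
    if sampling_rate is None:
        sampling_rate = inferred_rate
    elif abs(inferred_rate - sampling_rate) > 1e-6 * sampling_rate:
        raise GazeFormatError(
            f"timestamp step {step} ms inconsistent with sampling_rate "
            f"{sampling_rate} Hz")

    def channel(name: str) -> np.ndarray:
        return df[colmap[name]].to_numpy(dtype=float)

    pos = {name: channel(name) for name in ("x_l", "y_l", "x_r", "y_r")}
    if position_units == "px":
        if geometry is None:
            raise GazeFormatError("pixel-unit input requires a ScreenGeometry")
        cx, cy = geometry.screen_center_px
        for name in pos:
            center = cx if name.startswith("x") else cy
            pos[name] = pixels_to_degrees(pos[name] - center, geometry)
    elif position_units != "deg":
        raise GazeFormatError(f"unknown position_units {position_units!r}")

    pupil = {name: channel(name) for name in ("pupil_l", "pupil_r")}
    if pupil_missing_sentinel is not None:
        for name in pupil:
            p = pupil[name]
            p[p == pupil_missing_sentinel] = np.nan
            pupil[name] = p

    return GazeRecording(t_ms=t, sampling_rate=float(sampling_rate),
                         meta=dict(meta or {}), **pos, **pupil)


def intervals_to_frame(intervals: Sequence[tuple[int, int]],
                       **extra_columns) -> pd.DataFrame:
    """Tabulate half-open sample intervals, with optional constant columns."""
    df = pd.DataFrame(intervals, columns=["onset_sample", "offset_sample"])
    for key, value in extra_columns.items():
        df[key] = value
    return df
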