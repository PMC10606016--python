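"""Reading, calibration and trimming of array-pressure-sensor recordings.

The raw observable is a stack of per-frame force grids recorded by a
40 x 40 tactile array (1.9 mm pitch, 60 fps by default).  Two on-disk
dialects are accepted:

* a directory of per-frame CSV grids named ``frame_0001.csv``, ... ;
* a single long-format CSV with header ``frame,i,j,force_raw`` (1-based
  grid indices).  The long format is canonical for writing.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, NoContactError, ParameterError, ValidationError

__all__ = [
    "SensorSpec",
    "ImpactConfig",
    "CalibrationTable",
    "PressureFrameStack",
    "read_frame_stack",
    "write_frame_stack",
    "read_calibration",
    "write_calibration",
    "apply_calibration",
    "trim_to_effective_frames",
    "DEFAULT_FORCE_FLOOR",
]

#: Default total-force floor (N) separating contact frames from noise.
#: Small relative to the >= 8.75 N forces of interest.
DEFAULT_FORCE_FLOOR = 0.1

#: Gravitational acceleration used throughout (m s^-2).
GRAVITY = 9.8


@dataclass(frozen=True)
class SensorSpec:
    """Geometry and timing of the array pressure sensor."""

    rows: int = 40
    cols: int = 40
    pitch_mm: float = 1.9
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("sensor grid must have at least one row and column")
        if self.pitch_mm <= 0:
            raise ParameterError("sensor pitch must be positive")
        if self.frame_rate <= 0:
            raise ParameterError("frame rate must be positive")

    @property
    def frame_period(self) -> float:
        """Seconds per frame (1/Z)."""
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class ImpactConfig:
    """Drop-test parameters: height, hammer mass, gravity."""

    drop_height_m: float
    hammer_mass_kg: float = 0.5
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if self.drop_height_m <= 0:
            raise ParameterError("drop height must be positive")
        if self.hammer_mass_kg <= 0:
            raise ParameterError("hammer mass must be positive")
        if self.gravity <= 0:
            raise ParameterError("gravity must be positive")

    @property
    def impact_velocity(self) -> float:
        """Free-fall velocity at first contact, sqrt(2 g h) in m/s."""
        return float(np.sqrt(2.0 * self.gravity * self.drop_height_m))


@dataclass(frozen=True)
class CalibrationTable:
    """Per-sensing-point affine map from raw readings to force in N."""

    gain: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        gain = np.asarray(self.gain, dtype=float)
        offset = np.asarray(self.offset, dtype=float)
        if gain.shape != offset.shape:
            raise ValidationError("gain and offset shapes differ")
        if gain.ndim != 2:
            raise ValidationError("calibration table must be 2-D")
        if np.any(gain <= 0):
            raise ValidationError("calibration gains must be positive")
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "offset", offset)

    @classmethod
    def identity(cls, sensor: SensorSpec) -> "CalibrationTable":
        shape = (sensor.rows, sensor.cols)
        return cls(gain=np.ones(shape), offset=np.zeros(shape))


@dataclass(frozen=True)
class PressureFrameStack:
    """Time-ordered per-sensing-point force grids.

    ``forces`` has shape ``(n_frames, rows, cols)``; frame index runs from
    the first retained frame.  Values are non-negative forces in N (or raw
    sensor units before calibration).
    """

    forces: np.ndarray
    sensor: SensorSpec = field(default_factory=SensorSpec)

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        if forces.ndim != 3:
            raise FormatError("frame stack must be (frames, rows, cols)")
        if forces.shape[0] < 1:
            raise ValidationError("frame stack must contain at least one frame")
        if forces.shape[1:] != (self.sensor.rows, self.sensor.cols):
            raise FormatError(
                f"frame shape {forces.shape[1:]} does not match sensor grid "
                f"({self.sensor.rows}, {self.sensor.cols})"
            )
        if np.any(forces < 0):
            raise ValidationError("forces must be non-negative")
        object.__setattr__(self, "forces", forces)

    @property
    def n_frames(self) -> int:
        return int(self.forces.shape[0])

    def total_force_per_frame(self) -> np.ndarray:
        """Sum of all sensing points per frame, shape (n_frames,)."""
        return self.forces.sum(axis=(1, 2))

    def peak_force_map(self) -> np.ndarray:
        """Per-sensing-point maximum force over all frames."""
        return self.forces.max(axis=0)


_FRAME_FILE_RE = re.compile(r"frame_(\d+)\.csv$")


def _read_frame_dir(path: Path, sensor: SensorSpec) -> np.ndarray:
    entries = []
    for name in os.listdir(path):
        m = _FRAME_FILE_RE.match(name)
        if m:
            entries.append((int(m.group(1)), path / name))
    if not entries:
        raise FormatError(f"no frame_*.csv files found in {path}")
    entries.sort()
    frames = []
    for idx, fp in entries:
        grid = np.loadtxt(fp, delimiter=",", dtype=float, ndmin=2)
        if grid.shape != (sensor.rows, sensor.cols):
            raise FormatError(
                f"{fp.name}: frame shape {grid.shape} does not match sensor "
                f"grid ({sensor.rows}, {sensor.cols})"
            )
        frames.append(grid)
    return np.stack(frames)


def _read_long_table(path: Path, sensor: SensorSpec) -> np.ndarray:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV, binary junk, ...
        raise FormatError(f"{path}: unreadable frame table ({exc})") from exc
    required = {"frame", "i", "j"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns frame,i,j,force_raw")
    value_col = "force_raw" if "force_raw" in df.columns else "force_n"
    if value_col not in df.columns:
        raise FormatError(f"{path}: missing force column (force_raw or force_n)")
    try:
        frames = df["frame"].to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric frame indices") from exc
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    vals = df[value_col].to_numpy(dtype=float)
    if frames.min() < 1 or i.min() < 1 or j.min() < 1:
        raise FormatError(f"{path}: frame,i,j indices are 1-based")
    if i.max() > sensor.rows or j.max() > sensor.cols:
        raise FormatError(
            f"{path}: indices exceed sensor grid ({sensor.rows}, {sensor.cols})"
        )
    n_frames = int(frames.max())
    out = np.zeros((n_frames, sensor.rows, sensor.cols))
    out[frames - 1, i - 1, j - 1] = vals
    return out


def read_frame_stack(path: str | os.PathLike, sensor: SensorSpec | None = None) -> PressureFrameStack:
    """Read a frame stack from a directory of grids or a long-format CSV.

    Parameters
    ----------
    path
        Directory containing ``frame_*.csv`` grids, or a long-format CSV
        file with header ``frame,i,j,force_raw``.
    sensor
        Expected sensor geometry; defaults to the 40 x 40 / 1.9 mm / 60 fps
        array.

    Raises
    ------
    FormatError
        If a frame does not match the sensor grid shape.
    ValidationError
        If any raw value is negative.
    """
    sensor = sensor or SensorSpec()
    p = Path(path)
    if p.is_dir():
        forces = _read_frame_dir(p, sensor)
    else:
        forces = _read_long_table(p, sensor)
    if np.any(forces < 0):
        raise ValidationError(f"{p}: negative raw sensor values")
    return PressureFrameStack(forces=forces, sensor=sensor)


def write_frame_stack(stack: PressureFrameStack, path: str | os.PathLike) -> None:
    """Write a stack as the canonical long-format CSV (``frame,i,j,force_raw``).

    Only nonzero entries are stored; zeros are implicit.  The final frame
    always carries at least one row so the frame count round-trips.
    """
    n, rows, cols = stack.forces.shape
    f_idx, i_idx, j_idx = np.nonzero(stack.forces)
    vals = stack.forces[f_idx, i_idx, j_idx]
    if n - 1 not in f_idx:
        # anchor the last frame so n_frames survives the round trip
        f_idx = np.append(f_idx, n - 1)
        i_idx = np.append(i_idx, 0)
        j_idx = np.append(j_idx, 0)
        vals = np.append(vals, stack.forces[n - 1, 0, 0])
    df = pd.DataFrame(
        {
            "frame": f_idx + 1,
            "i": i_idx + 1,
            "j": j_idx + 1,
            "force_raw": vals,
        }
    )
    df.to_csv(path, index=False)


def read_calibration(path: str | os.PathLike, sensor: SensorSpec | None = None) -> CalibrationTable:
    """Read a per-point calibration CSV with header ``i,j,gain,offset``."""
    sensor = sensor or SensorSpec()
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"i", "j", "gain", "offset"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns i,j,gain,offset")
    gain = np.full((sensor.rows, sensor.cols), np.nan)
    offset = np.full((sensor.rows, sensor.cols), np.nan)
    i = df["i"].to_numpy(dtype=int) - 1
    j = df["j"].to_numpy(dtype=int) - 1
    if i.min() < 0 or j.min() < 0 or i.max() >= sensor.rows or j.max() >= sensor.cols:
        raise FormatError(f"{path}: calibration indices outside sensor grid")
    gain[i, j] = df["gain"].to_numpy(dtype=float)
    offset[i, j] = df["offset"].to_numpy(dtype=float)
    if np.any(np.isnan(gain)):
        raise FormatError(f"{path}: calibration does not cover every sensing point")
    return CalibrationTable(gain=gain, offset=offset)


def write_calibration(cal: CalibrationTable, path: str | os.PathLike) -> None:
    rows, cols = cal.gain.shape
    i, j = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    df = pd.DataFrame(
        {
            "i": i.ravel() + 1,
            "j": j.ravel() + 1,
            "gain": cal.gain.ravel(),
            "offset": cal.offset.ravel(),
        }
    )
    df.to_csv(path, index=False)


def fit_calibration(
    raw_stacks: list[PressureFrameStack], known_forces_n: list[float]
) -> CalibrationTable:
    """Fit a per-point affine calibration from uniform-load block recordings.

    Each stack holds frames recorded under a calibration block applying a
    known per-point force; the per-point time averages of the recordings
    are regressed (least squares) against the known forces.

    Requires at least two distinct load levels.
    """
    if len(raw_stacks) != len(known_forces_n):
        raise ValidationError("one known force per calibration recording required")
    if len(set(known_forces_n)) < 2:
        raise ValidationError("need at least two distinct load levels")
    means = np.stack([s.forces.mean(axis=0) for s in raw_stacks])  # (L, rows, cols)
    targets = np.asarray(known_forces_n, dtype=float)
    x_mean = means.mean(axis=0)
    y_mean = targets.mean()
    cov = ((means - x_mean) * (targets[:, None, None] - y_mean)).sum(axis=0)
    var = ((means - x_mean) ** 2).sum(axis=0)
    if np.any(var <= 0):
        raise ValidationError("a sensing point shows no response across load levels")
    gain = cov / var
    offset = y_mean - gain * x_mean
    return CalibrationTable(gain=gain, offset=offset)


def apply_calibration(raw: PressureFrameStack, cal: CalibrationTable) -> PressureFrameStack:
    """Map raw readings to forces: ``gain * raw + offset``, floored at 0 N."""
    if cal.gain.shape != raw.forces.shape[1:]:
        raise ValidationError(
            f"calibration shape {cal.gain.shape} does not match stack grid "
            f"{raw.forces.shape[1:]}"
        )
    calibrated = cal.gain[None, :, :] * raw.forces + cal.offset[None, :, :]
    np.clip(calibrated, 0.0, None, out=calibrated)
    return PressureFrameStack(forces=calibrated, sensor=raw.sensor)


def trim_to_effective_frames(
    stack: PressureFrameStack, force_floor: float = DEFAULT_FORCE_FLOOR
) -> PressureFrameStack:
    """Trim leading/trailing frames whose total force is at or below the floor.

    The contact window is assumed contiguous: frames *inside* the window
    that dip below the floor (contact chatter) are retained; only the
    window edges are removed.  The first retained frame becomes frame 1.

    Raises
    ------
    NoContactError
        If no frame exceeds the floor.
    """
    if force_floor < 0:
        raise ParameterError("force floor must be non-negative")
    totals = stack.total_force_per_frame()
    above = np.nonzero(totals > force_floor)[0]
    if above.size == 0:
        raise NoContactError(
            f"no frame exceeds the contact floor of {force_floor} N"
        )
    first, last = int(above[0]), int(above[-1])
    if first == 0 and last == stack.n_frames - 1:
        return stack
    return replace(stack, forces=stack.forces[first : last + 1])
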