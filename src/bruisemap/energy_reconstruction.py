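"""Hammer kinematics and absorbed-energy maps from force frame stacks.

The hammer enters the first effective frame at its free-fall velocity
``V_1 = sqrt(2 g h)``.  Subsequent per-frame velocities follow from the
measured impulse:

    V_f = V_1 - (1 / (m Z)) * sum_{x=1}^{f-1} sum_{i,j} F(i, j, x)

the per-frame travel is ``S_f = V_f / Z``, and the energy absorbed at a
sensing point is the force-times-travel sum ``E(i,j) = sum_x F(i,j,x) S_x``.

The impulse bookkeeping can drive ``V_f`` negative (restitution is not
modelled); the series is truncated at the last frame with positive
velocity so that no sensing point is ever *debited* energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NoImpactError, ParameterError, ValidationError
from .pressure_io import ImpactConfig, PressureFrameStack, SensorSpec

__all__ = [
    "KinematicsSeries",
    "EnergyMap",
    "EnergyProfile",
    "velocity_series",
    "energy_map",
    "energy_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinematicsSeries:
    """Per-effective-frame hammer velocity (m/s) and travel (m)."""

    velocity: np.ndarray
    displacement: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity, dtype=float)
        s = np.asarray(self.displacement, dtype=float)
        if v.shape != s.shape or v.ndim != 1:
            raise ValidationError("velocity and displacement must be equal-length 1-D")
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "displacement", s)

    @property
    def n_frames(self) -> int:
        return int(self.velocity.size)


@dataclass(frozen=True)
class EnergyMap:
    """Absorbed impact energy per sensing point (J)."""

    energy: np.ndarray
    sensor: SensorSpec

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        if e.shape != (self.sensor.rows, self.sensor.cols):
            raise ValidationError("energy map shape does not match sensor grid")
        if np.any(e < 0):
            raise ValidationError("absorbed energies must be non-negative")
        object.__setattr__(self, "energy", e)

    @property
    def total(self) -> float:
        return float(self.energy.sum())


@dataclass(frozen=True)
class EnergyProfile:
    """1-D axial slice of an energy map through the impact centre.

    ``positions_mm`` are lateral positions along the slice at sensor
    pitch; ``center_index`` is the index of the impact centre within the
    profile arrays.
    """

    positions_mm: np.ndarray
    energy_j: np.ndarray
    center_index: int

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_mm, dtype=float)
        e = np.asarray(self.energy_j, dtype=float)
        if p.shape != e.shape or p.ndim != 1:
            raise ValidationError("profile arrays must be equal-length 1-D")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValidationError("profile positions must be strictly increasing")
        if not (0 <= self.center_index < p.size):
            raise ValidationError("center index outside the profile")
        object.__setattr__(self, "positions_mm", p)
        object.__setattr__(self, "energy_j", e)

    @property
    def center_position_mm(self) -> float:
        return float(self.positions_mm[self.center_index])


def velocity_series(stack: PressureFrameStack, cfg: ImpactConfig) -> KinematicsSeries:
    """Per-frame hammer velocity and travel from the total force history.

    The stack must already be trimmed to the effective contact window.
    The series is truncated at the last frame with positive velocity;
    ``truncated`` records whether truncation occurred.
    """
    if cfg.drop_height_m <= 0 or cfg.hammer_mass_kg <= 0:
        raise ParameterError("drop height and hammer mass must be positive")
    z = stack.sensor.frame_rate
    v1 = cfg.impact_velocity
    totals = stack.total_force_per_frame()
    # V_f depends on the impulse accumulated over frames 1 .. f-1
    impulse = np.concatenate(([0.0], np.cumsum(totals)[:-1])) / z
    velocity = v1 - impulse / cfg.hammer_mass_kg
    positive = np.nonzero(velocity > 0)[0]
    truncated = positive.size < velocity.size
    if truncated:
        # contiguous prefix: velocity is non-increasing for F >= 0
        velocity = velocity[: positive[-1] + 1]
        logger.warning(
            "velocity series truncated at frame %d of %d (impulse exceeded m*V1)",
            velocity.size,
            stack.n_frames,
        )
    displacement = velocity / z
    return KinematicsSeries(velocity=velocity, displacement=displacement, truncated=truncated)


def energy_map(stack: PressureFrameStack, kin: KinematicsSeries) -> EnergyMap:
    """Absorbed energy per sensing point: ``E(i,j) = sum_x F(i,j,x) * S_x``.

    The sum runs over the frames shared by the stack and the (possibly
    truncated) kinematics series.
    """
    n = min(stack.n_frames, kin.n_frames)
    if kin.n_frames > stack.n_frames:
        raise ValidationError(
            "kinematics series is longer than the frame stack it came from"
        )
    energy = np.einsum("fij,f->ij", stack.forces[:n], kin.displacement[:n])
    return EnergyMap(energy=energy, sensor=stack.sensor)


def _auto_center(energy: np.ndarray) -> tuple[int, int]:
    """Grid argmax of E; ties broken toward the grid centroid."""
    peak = energy.max()
    if peak <= 0:
        raise NoImpactError("energy map is all zero; no impact centre to locate")
    rows, cols = np.nonzero(energy == peak)
    if rows.size == 1:
        return int(rows[0]), int(cols[0])
    cr = (energy.shape[0] - 1) / 2.0
    cc = (energy.shape[1] - 1) / 2.0
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    k = int(np.argmin(d2))
    return int(rows[k]), int(cols[k])


def energy_profile(
    emap: EnergyMap,
    axis: str = "row",
    center: tuple[int, int] | str = "auto",
) -> EnergyProfile:
    """Slice the energy map through the impact centre.

    Parameters
    ----------
    emap
        Energy map to slice.
    axis
        ``"row"`` slices along the centre row (varying column); ``"col"``
        slices along the centre column (varying row).
    center
        ``(row, col)`` grid coordinate (0-based), or ``"auto"`` to use the
        grid argmax of E with ties broken toward the grid centroid.
    """
    if axis not in ("row", "col"):
        raise ParameterError("axis must be 'row' or 'col'")
    if center == "auto":
        r, c = _auto_center(emap.energy)
    else:
        r, c = int(center[0]), int(center[1])
        if not (0 <= r < emap.sensor.rows and 0 <= c < emap.sensor.cols):
            raise ParameterError("impact centre outside the sensor grid")
    pitch = emap.sensor.pitch_mm
    if axis == "row":
        values = emap.energy[r, :]
        center_index = c
    else:
        values = emap.energy[:, c]
        center_index = r
    positions = np.arange(values.size, dtype=float) * pitch
    return EnergyProfile(
        positions_mm=positions, energy_j=values.copy(), center_index=center_index
    )
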