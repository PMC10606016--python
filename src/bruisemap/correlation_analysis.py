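"""Depth-vs-energy correlation of registered damage and energy profiles.

The damage profile (mm grid, image frame) is resampled to the sensor
pitch and aligned with the energy profile either through metadata
centres or by matching the two profile peaks.  Per-sample Pearson r is
computed for depth-vs-energy and width-vs-energy, with optional
exclusion of sensing points whose peak force never reached the
biological yield force (8.75 N).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage_metrics import DamageProfile, resample_profile
from .energy_reconstruction import EnergyProfile
from .errors import DegenerateSeriesError, ParameterError, RegistrationError, ValidationError

__all__ = [
    "AnalysisConfig",
    "PairedProfiles",
    "CorrelationResult",
    "HeightSummary",
    "register_profiles",
    "pearson_r",
    "apply_yield_mask",
    "correlate",
    "summarize_by_height",
    "write_results",
    "write_height_summary",
]

#: Biological yield force of the fruit tissue (N).
DEFAULT_YIELD_FORCE = 8.75


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for registration, masking and correlation."""

    yield_force_n: float = DEFAULT_YIELD_FORCE
    mask_sub_yield: bool = False
    registration: str = "metadata"  # or "peak_align"
    pitch_mm: float = 1.9
    method: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if self.yield_force_n <= 0:
            raise ParameterError("yield force must be positive")
        if self.pitch_mm <= 0:
            raise ParameterError("pitch must be positive")
        if self.registration not in ("metadata", "peak_align"):
            raise ParameterError("registration must be 'metadata' or 'peak_align'")
        if self.method not in ("pearson", "spearman"):
            raise ParameterError("method must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class PairedProfiles:
    """Registered (depth, width, energy) vectors over the common support."""

    depth_mm: np.ndarray
    width_mm: np.ndarray
    energy_j: np.ndarray
    offsets_mm: np.ndarray  # lateral offset of each point from the impact centre

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, float)
        w = np.asarray(self.width_mm, float)
        e = np.asarray(self.energy_j, float)
        o = np.asarray(self.offsets_mm, float)
        if not (d.shape == w.shape == e.shape == o.shape) or d.ndim != 1:
            raise ValidationError("paired series must be equal-length 1-D")
        object.__setattr__(self, "depth_mm", d)
        object.__setattr__(self, "width_mm", w)
        object.__setattr__(self, "energy_j", e)
        object.__setattr__(self, "offsets_mm", o)

    @property
    def n_points(self) -> int:
        return int(self.depth_mm.size)


@dataclass(frozen=True)
class CorrelationResult:
    """Per-sample correlation of depth/width against the energy profile."""

    r_depth: float
    r_width: float
    n_points: int
    height_m: float
    masked_points: int = 0
    sample_id: str = ""


@dataclass(frozen=True)
class HeightSummary:
    """Distribution of per-sample r values grouped by drop height."""

    height_m: float
    r_depth_values: np.ndarray
    r_width_values: np.ndarray
    r_depth_min: float = field(init=False)
    r_depth_max: float = field(init=False)
    r_depth_mean: float = field(init=False)
    r_width_min: float = field(init=False)
    r_width_max: float = field(init=False)
    r_width_mean: float = field(init=False)

    def __post_init__(self) -> None:
        rd = np.asarray(self.r_depth_values, float)
        rw = np.asarray(self.r_width_values, float)
        object.__setattr__(self, "r_depth_values", rd)
        object.__setattr__(self, "r_width_values", rw)
        for name, vals in (("r_depth", rd), ("r_width", rw)):
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                mn = mx = mean = float("nan")
            else:
                mn, mx, mean = float(finite.min()), float(finite.max()), float(finite.mean())
            object.__setattr__(self, f"{name}_min", mn)
            object.__setattr__(self, f"{name}_max", mx)
            object.__setattr__(self, f"{name}_mean", mean)

    @property
    def r_depth_range(self) -> float:
        return self.r_depth_max - self.r_depth_min


def register_profiles(
    damage: DamageProfile,
    energy: EnergyProfile,
    cfg: AnalysisConfig | None = None,
    damage_center_mm: float | None = None,
    include_undefined_as_zero: bool = True,
) -> PairedProfiles:
    """Resample the damage profile to sensor pitch and pair it with energy.

    With ``registration="metadata"`` the damage-frame position
    ``damage_center_mm`` is mapped onto the energy profile's centre; with
    ``"peak_align"`` the depth peak is mapped onto the energy peak.
    ``include_undefined_as_zero`` keeps zero-depth (no-zone) positions in
    the pairing — the convention for sub-yield sites — instead of
    dropping them.

    Raises
    ------
    RegistrationError
        If the profiles overlap on fewer than 3 points.
    """
    cfg = cfg or AnalysisConfig()
    if damage.n_defined < 2:
        raise RegistrationError("damage profile has fewer than 2 defined points")
    if cfg.registration == "metadata":
        if damage_center_mm is None:
            raise ParameterError("metadata registration needs damage_center_mm")
        center = float(damage_center_mm)
    else:
        defined = damage.defined
        center = float(damage.lateral_mm[defined][np.argmax(damage.depth_mm[defined])])

    # already on a pitch grid anchored at the centre? then pair positionally
    on_grid = False
    if damage.lateral_mm.size > 1:
        rel = (damage.lateral_mm - center) / cfg.pitch_mm
        on_grid = np.allclose(rel, np.round(rel), atol=1e-9)
    resampled = damage if on_grid else resample_profile(damage, cfg.pitch_mm, center)

    energy_offsets = energy.positions_mm - energy.center_position_mm
    damage_offsets = resampled.lateral_mm - center
    # match by integer pitch step
    e_steps = np.round(energy_offsets / cfg.pitch_mm).astype(int)
    d_steps = np.round(damage_offsets / cfg.pitch_mm).astype(int)
    common, e_idx, d_idx = np.intersect1d(e_steps, d_steps, return_indices=True)
    if not include_undefined_as_zero:
        keep = resampled.defined[d_idx]
        common, e_idx, d_idx = common[keep], e_idx[keep], d_idx[keep]
    if common.size < 3:
        raise RegistrationError(
            f"profiles overlap on only {common.size} points (need >= 3)"
        )
    return PairedProfiles(
        depth_mm=resampled.depth_mm[d_idx],
        width_mm=resampled.width_mm[d_idx],
        energy_j=energy.energy_j[e_idx],
        offsets_mm=common * cfg.pitch_mm,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Returns NaN (the flagged "undefined" value) when either series has
    zero variance.

    Raises
    ------
    ValidationError
        On length mismatch or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("need at least 3 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.dot(xc, yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    import warnings

    from scipy import stats

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def apply_yield_mask(
    paired: PairedProfiles,
    peak_force_profile: np.ndarray,
    cfg: AnalysisConfig,
) -> tuple[PairedProfiles, int]:
    """Drop points whose peak contact force stayed below the yield force.

    A no-op (masked count 0) when ``cfg.mask_sub_yield`` is off.  Returns
    the filtered pairing and the number of points removed.

    Raises
    ------
    DegenerateSeriesError
        If masking removes every point.
    """
    peak = np.asarray(peak_force_profile, dtype=float)
    if peak.shape != paired.depth_mm.shape:
        raise ValidationError("peak force profile must align with the paired series")
    if not cfg.mask_sub_yield:
        return paired, 0
    keep = peak >= cfg.yield_force_n
    n_masked = int((~keep).sum())
    if not keep.any():
        raise DegenerateSeriesError("yield mask removed every point")
    return (
        PairedProfiles(
            depth_mm=paired.depth_mm[keep],
            width_mm=paired.width_mm[keep],
            energy_j=paired.energy_j[keep],
            offsets_mm=paired.offsets_mm[keep],
        ),
        n_masked,
    )


def correlate(
    paired: PairedProfiles,
    height_m: float,
    cfg: AnalysisConfig | None = None,
    masked_points: int = 0,
    sample_id: str = "",
) -> CorrelationResult:
    """Depth-vs-energy and width-vs-energy correlation for one sample."""
    cfg = cfg or AnalysisConfig()
    if paired.n_points < 3:
        raise ValidationError("need at least 3 paired points")
    stat = pearson_r if cfg.method == "pearson" else _spearman_r
    return CorrelationResult(
        r_depth=stat(paired.depth_mm, paired.energy_j),
        r_width=stat(paired.width_mm, paired.energy_j),
        n_points=paired.n_points,
        height_m=height_m,
        masked_points=masked_points,
        sample_id=sample_id,
    )


def summarize_by_height(results: list[CorrelationResult]) -> list[HeightSummary]:
    """Group per-sample results by drop height; min/max/mean of r each."""
    if not results:
        raise ValidationError("no correlation results to summarize")
    heights = sorted({res.height_m for res in results})
    out = []
    for h in heights:
        group = [res for res in results if res.height_m == h]
        out.append(
            HeightSummary(
                height_m=h,
                r_depth_values=np.array([res.r_depth for res in group]),
                r_width_values=np.array([res.r_width for res in group]),
            )
        )
    return out


def write_results(results: list[CorrelationResult], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": res.sample_id,
                "height_m": res.height_m,
                "r_depth": res.r_depth,
                "r_width": res.r_width,
                "n_points": res.n_points,
                "masked_points": res.masked_points,
            }
            for res in results
        ]
    ).to_csv(path, index=False)


def write_height_summary(summaries: list[HeightSummary], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "height_m": s.height_m,
                "n_samples": s.r_depth_values.size,
                "r_depth_min": s.r_depth_min,
                "r_depth_max": s.r_depth_max,
                "r_depth_mean": s.r_depth_mean,
                "r_width_min": s.r_width_min,
                "r_width_max": s.r_width_max,
                "r_width_mean": s.r_width_mean,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)
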