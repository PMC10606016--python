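"""Depth and width profiles of the death zone.

Per image column the mask decomposes into vertical runs with half-open
boundaries ``[start, end)``.  The zone centre for the depth measurement
is the midpoint of the two outermost boundaries — for the two-run case
with boundaries ``(Y1, Y2, Y3, Y4)`` that is ``(Y1 + Y4) / 2`` — and the
width is the summed length of all runs, ``(Y2 - Y1) + (Y4 - Y3)``.
Depth is measured from the peel surface along the image depth axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ResamplingError, ValidationError
from .section_imaging import DeathZoneMask, PeelCurve

__all__ = [
    "ZoneSegments",
    "DamageProfile",
    "column_segments",
    "depth_and_width",
    "resample_profile",
    "write_damage_profile",
    "read_damage_profile",
]


@dataclass(frozen=True)
class ZoneSegments:
    """Per-column run boundaries of the mask along the depth axis.

    ``columns[x]`` is a list of ``(start, end)`` half-open pixel-row runs,
    ordered and disjoint; empty where the column has no foreground.
    """

    columns: list[list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for x, runs in enumerate(self.columns):
            prev_end = -1
            for start, end in runs:
                if not (prev_end < start < end):
                    raise ValidationError(f"column {x}: runs not strictly increasing")
                prev_end = end

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class DamageProfile:
    """Per-lateral-position depth and width of the death zone, in mm.

    ``defined`` is False where no zone was measured; such positions carry
    depth 0 / width 0 (the zero-depth convention for sub-yield sites) but
    keep the flag so downstream code can select either behaviour.
    """

    lateral_mm: np.ndarray
    depth_mm: np.ndarray
    width_mm: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lateral_mm, dtype=float)
        dep = np.asarray(self.depth_mm, dtype=float)
        wid = np.asarray(self.width_mm, dtype=float)
        flag = np.asarray(self.defined, dtype=bool)
        if not (lat.shape == dep.shape == wid.shape == flag.shape) or lat.ndim != 1:
            raise ValidationError("profile arrays must be equal-length 1-D")
        if lat.size > 1 and np.any(np.diff(lat) <= 0):
            raise ValidationError("lateral positions must be strictly increasing")
        if np.any(dep[flag] < 0) or np.any(wid[flag] < 0):
            raise ValidationError("depth and width must be non-negative where defined")
        object.__setattr__(self, "lateral_mm", lat)
        object.__setattr__(self, "depth_mm", dep)
        object.__setattr__(self, "width_mm", wid)
        object.__setattr__(self, "defined", flag)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


def column_segments(mask: DeathZoneMask) -> ZoneSegments:
    """Run-length boundaries of the mask foreground, column by column."""
    m = mask.mask
    h, w = m.shape
    padded = np.zeros((h + 2, w), dtype=np.int8)
    padded[1:-1] = m
    diff = np.diff(padded, axis=0)
    columns: list[list[tuple[int, int]]] = []
    for x in range(w):
        starts = np.nonzero(diff[:, x] == 1)[0]
        ends = np.nonzero(diff[:, x] == -1)[0]
        columns.append(list(zip(starts.tolist(), ends.tolist())))
    return ZoneSegments(columns=columns)


def depth_and_width(
    segs: ZoneSegments, peel: PeelCurve, scale_mm_per_px: float
) -> DamageProfile:
    """Depth (peel to zone centre) and width (summed run length) per column.

    Columns with no runs, or without a defined peel surface, are flagged
    undefined and carry depth 0 / width 0.

    Raises
    ------
    ValidationError
        If a zone centre lies above the peel surface (impossible geometry).
    """
    if scale_mm_per_px <= 0:
        raise ParameterError("scale must be positive")
    if peel.y_peel.size != segs.n_columns:
        raise ValidationError("peel curve and segments cover different column counts")
    n = segs.n_columns
    depth = np.zeros(n)
    width = np.zeros(n)
    flag = np.zeros(n, dtype=bool)
    for x, runs in enumerate(segs.columns):
        if not runs or np.isnan(peel.y_peel[x]):
            continue
        first = runs[0][0]
        last = runs[-1][1]
        center = (first + last) / 2.0
        if center < peel.y_peel[x]:
            raise ValidationError(
                f"column {x}: zone centre {center} above peel {peel.y_peel[x]}"
            )
        depth[x] = (center - peel.y_peel[x]) * scale_mm_per_px
        width[x] = sum(end - start for start, end in runs) * scale_mm_per_px
        flag[x] = True
    lateral = np.arange(n, dtype=float) * scale_mm_per_px
    return DamageProfile(lateral_mm=lateral, depth_mm=depth, width_mm=width, defined=flag)


def resample_profile(
    profile: DamageProfile, pitch_mm: float, center_mm: float
) -> DamageProfile:
    """Linearly resample depth/width onto a grid at ``pitch_mm`` spacing.

    The output grid is centred at ``center_mm`` and spans the measured
    support; positions outside the defined support are flagged undefined.

    Raises
    ------
    ResamplingError
        If fewer than 2 defined points exist.
    """
    if pitch_mm <= 0:
        raise ParameterError("pitch must be positive")
    idx = np.nonzero(profile.defined)[0]
    if idx.size < 2:
        raise ResamplingError("need at least 2 defined points to resample")
    x = profile.lateral_mm[idx]
    lo, hi = x[0], x[-1]
    k_lo = int(np.ceil((lo - center_mm) / pitch_mm - 1e-9))
    k_hi = int(np.floor((hi - center_mm) / pitch_mm + 1e-9))
    span_lo = min(k_lo, 0)
    span_hi = max(k_hi, 0)
    ks = np.arange(span_lo, span_hi + 1)
    new_x = center_mm + ks * pitch_mm
    inside = (new_x >= lo - 1e-9) & (new_x <= hi + 1e-9)
    depth = np.zeros(new_x.size)
    width = np.zeros(new_x.size)
    depth[inside] = np.interp(new_x[inside], x, profile.depth_mm[idx])
    width[inside] = np.interp(new_x[inside], x, profile.width_mm[idx])
    return DamageProfile(
        lateral_mm=new_x, depth_mm=depth, width_mm=width, defined=inside
    )


def write_damage_profile(profile: DamageProfile, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "lateral_mm": profile.lateral_mm,
            "depth_mm": profile.depth_mm,
            "width_mm": profile.width_mm,
            "defined_flag": profile.defined.astype(int),
        }
    ).to_csv(path, index=False)


def read_damage_profile(path: str | os.PathLike) -> DamageProfile:
    df = pd.read_csv(path)
    return DamageProfile(
        lateral_mm=df["lateral_mm"].to_numpy(float),
        depth_mm=df["depth_mm"].to_numpy(float),
        width_mm=df["width_mm"].to_numpy(float),
        defined=df["defined_flag"].to_numpy(bool),
    )
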