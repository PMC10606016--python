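"""Death-zone segmentation and peel tracing for stained tissue sections.

The discriminant for dead tissue is the HSV saturation channel: trypan
blue stains dead cells strongly, so the death band is a high-saturation
region against a weakly saturated tissue mosaic.  Segmentation is
threshold (Otsu by default) -> morphological opening -> closing ->
largest 8-connected component -> hole filling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread as _imread
from imageio.v3 import imwrite as _imwrite
from scipy import ndimage
from skimage import color, filters, morphology

from .errors import FormatError, NoTissueError, NoZoneError, ParameterError, ValidationError

__all__ = [
    "SectionImage",
    "DeathZoneMask",
    "PeelCurve",
    "saturation_channel",
    "segment_death_zone",
    "trace_peel",
    "read_section",
    "write_section",
    "write_mask",
]


@dataclass(frozen=True)
class SectionImage:
    """RGB tissue-section micrograph with physical scale and orientation.

    Pixel values are normalised to float in [0, 1] on construction;
    8-bit and 16-bit inputs are accepted.  ``peel_side`` says from which
    image edge the peel surface is approached ("top" or "bottom").
    """

    rgb: np.ndarray
    scale_mm_per_px: float
    peel_side: str = "top"

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise FormatError("section image must be RGB (H, W, 3)")
        if rgb.shape[0] == 0 or rgb.shape[1] == 0:
            raise ValidationError("section image is empty")
        if rgb.dtype == np.uint8:
            rgb = rgb.astype(float) / 255.0
        elif rgb.dtype == np.uint16:
            rgb = rgb.astype(float) / 65535.0
        else:
            rgb = rgb.astype(float)
            if rgb.max() > 1.0 + 1e-9:
                raise ValidationError("float images must already be in [0, 1]")
        if self.scale_mm_per_px <= 0:
            raise ValidationError("scale must be positive")
        if self.peel_side not in ("top", "bottom"):
            raise ParameterError("peel_side must be 'top' or 'bottom'")
        object.__setattr__(self, "rgb", rgb)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[0], self.rgb.shape[1]


@dataclass(frozen=True)
class DeathZoneMask:
    """Binary death-zone mask plus the parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValidationError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PeelCurve:
    """Per-column peel-surface row, NaN on columns without tissue."""

    y_peel: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y_peel, dtype=float)
        if y.ndim != 1:
            raise ValidationError("peel curve must be 1-D")
        object.__setattr__(self, "y_peel", y)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.y_peel)


def saturation_channel(img: SectionImage) -> np.ndarray:
    """HSV saturation channel of the section, float in [0, 1]."""
    return color.rgb2hsv(img.rgb)[:, :, 1]


def segment_death_zone(
    s_channel: np.ndarray,
    threshold: float | str = "otsu",
    open_radius: int = 3,
    close_radius: int = 5,
) -> DeathZoneMask:
    """Segment the death zone from a saturation channel.

    Binarise at ``threshold`` (Otsu when ``"otsu"``), open then close with
    disk structuring elements, keep the largest 8-connected component and
    fill its holes.  The result has exactly one connected foreground
    component and no interior holes.

    Raises
    ------
    NoZoneError
        If thresholding (or the morphology) leaves no foreground.
    """
    s = np.asarray(s_channel, dtype=float)
    if s.ndim != 2:
        raise FormatError("saturation channel must be 2-D")
    if s.min() < -1e-9 or s.max() > 1.0 + 1e-9:
        raise ValidationError("saturation channel must lie in [0, 1]")
    if threshold == "otsu":
        if np.allclose(s, s.flat[0]):
            raise NoZoneError("constant saturation channel; nothing to segment")
        thr = float(filters.threshold_otsu(s))
    else:
        thr = float(threshold)
    binary = s > thr
    if open_radius > 0:
        binary = morphology.opening(binary, morphology.disk(open_radius))
    if close_radius > 0:
        binary = morphology.closing(binary, morphology.disk(close_radius))
    if not binary.any():
        raise NoZoneError("no death zone detected after thresholding and morphology")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        binary = labels == keep
    binary = ndimage.binary_fill_holes(binary)
    return DeathZoneMask(
        mask=binary,
        provenance={
            "threshold": thr,
            "threshold_method": "otsu" if threshold == "otsu" else "manual",
            "open_radius": open_radius,
            "close_radius": close_radius,
            "connectivity": 8,
        },
    )


def trace_peel(
    img: SectionImage,
    background_threshold: float | str = "otsu",
    median_window: int = 11,
) -> PeelCurve:
    """Trace the peel surface: per column, the first tissue pixel from the
    peel side, smoothed by a running median.

    Tissue is separated from the (dark) mounting background on overall
    intensity; the threshold is Otsu on the grayscale image by default.

    Raises
    ------
    NoTissueError
        If no column contains tissue.
    """
    gray = img.rgb.mean(axis=2)
    if background_threshold == "otsu":
        if np.allclose(gray, gray.flat[0]):
            raise NoTissueError("image has no tissue/background boundary")
        thr = float(filters.threshold_otsu(gray))
    else:
        thr = float(background_threshold)
    tissue = gray > thr
    if not tissue.any():
        raise NoTissueError("no tissue pixels above the background threshold")
    h, w = tissue.shape
    scan = tissue if img.peel_side == "top" else tissue[::-1]
    has_tissue = scan.any(axis=0)
    first = scan.argmax(axis=0).astype(float)
    if img.peel_side == "bottom":
        first = (h - 1) - first
    first[~has_tissue] = np.nan
    if not has_tissue.any():
        raise NoTissueError("no column contains tissue")
    # running median smooths stain speckle on the surface; NaN columns stay NaN
    if median_window > 1:
        smoothed = first.copy()
        half = median_window // 2
        idx = np.nonzero(has_tissue)[0]
        for x in idx:
            lo, hi = max(0, x - half), min(w, x + half + 1)
            window = first[lo:hi]
            smoothed[x] = np.nanmedian(window)
        first = smoothed
    return PeelCurve(y_peel=first)


# ---------------------------------------------------------------------------
# I/O: TIFF/PNG images with a YAML/JSON sidecar carrying scale + orientation


def _sidecar_path(path: Path) -> Path | None:
    for ext in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    return None


def read_section(
    path: str | os.PathLike,
    scale_mm_per_px: float | None = None,
    peel_side: str | None = None,
) -> SectionImage:
    """Read a TIFF/PNG section image; scale and orientation come from a
    sidecar YAML/JSON (``scale_mm_per_px``, ``peel_side``) unless given."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        rgb = tifffile.imread(p)
    else:
        rgb = _imread(p)
    meta: dict = {}
    sidecar = _sidecar_path(p)
    if sidecar is not None:
        text = sidecar.read_text()
        meta = json.loads(text) if sidecar.suffix == ".json" else yaml.safe_load(text)
    scale = scale_mm_per_px if scale_mm_per_px is not None else meta.get("scale_mm_per_px")
    if scale is None:
        raise FormatError(f"{p}: no scale_mm_per_px given and no sidecar found")
    side = peel_side if peel_side is not None else meta.get("peel_side", "top")
    return SectionImage(rgb=rgb, scale_mm_per_px=float(scale), peel_side=side)


def write_section(img: SectionImage, path: str | os.PathLike) -> None:
    """Write the image (8-bit TIFF/PNG) plus a YAML sidecar with metadata."""
    p = Path(path)
    rgb8 = (np.clip(img.rgb, 0, 1) * 255).round().astype(np.uint8)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, rgb8)
    else:
        _imwrite(p, rgb8)
    sidecar = p.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {"scale_mm_per_px": float(img.scale_mm_per_px), "peel_side": img.peel_side}
        )
    )


def write_mask(mask: DeathZoneMask, path: str | os.PathLike) -> None:
    """Write the mask as an 8-bit image (0/255)."""
    p = Path(path)
    m8 = (mask.mask.astype(np.uint8)) * 255
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, m8)
    else:
        _imwrite(p, m8)
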