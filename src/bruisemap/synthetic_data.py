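"""Synthetic inputs with exact ground truth.

Three generators feed the pipeline:

* :func:`simulate_impact` — a spring/damper contact model integrated at a
  fine timestep.  Contact force follows ``F = k * delta**1.5 + c * ddelta``
  (clamped at 0) and is spread over the sensor grid with a Hertzian
  ``sqrt(1 - r^2/a^2)`` footprint, then binned to sensor frames.  The
  synthetic "fruit" is deliberately soft so that a 60 fps sensor resolves
  contact over many frames.
* :func:`render_section` — a stained-section image: dark mounting
  background, a cell-mosaic tissue texture (dense small cells near the
  surface, larger parenchyma below), sparse blue speckle from
  section-prep cell death, and a programmed high-saturation blue band.
* :func:`make_coupled_sample` — couples the two: the band depth tracks
  the absorbed-energy profile linearly with height-dependent noise,
  while the band width is drawn independently of energy.

Everything is seed-deterministic: identical parameters and seed produce
bit-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree
from skimage.color import hsv2rgb

from .damage_metrics import DamageProfile
from .energy_reconstruction import EnergyMap, EnergyProfile
from .errors import ParameterError, SimulationError, ValidationError
from .pressure_io import GRAVITY, PressureFrameStack, SensorSpec, write_frame_stack
from .section_imaging import PeelCurve, SectionImage, write_section

__all__ = [
    "SimulatorParams",
    "SectionParams",
    "CoupledSampleTruth",
    "KinematicsTruth",
    "SimulationResult",
    "SectionSample",
    "CoupledSample",
    "simulate_impact",
    "render_section",
    "make_coupled_sample",
    "write_coupled_sample",
]


@dataclass(frozen=True)
class SimulatorParams:
    """Drop-impact simulator parameters.

    ``contact_stiffness`` (N m^-1.5) and ``damping`` (N s/m) define the
    contact law; ``contact_radius_coeff`` maps penetration to footprint
    radius (``a = coeff * sqrt(delta)``, capped at ``contact_radius_max_m``).
    """

    drop_height_m: float
    hammer_mass_kg: float = 0.5
    contact_stiffness: float = 40.0
    damping: float = 5.0
    fine_dt: float = 2e-5
    sensor: SensorSpec = field(default_factory=SensorSpec)
    contact_center: tuple[int, int] | None = None
    contact_radius_coeff: float = 0.08
    contact_radius_max_m: float = 0.034
    penetration_cap_m: float = 0.25
    max_time_s: float = 1.2
    gravity: float = GRAVITY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_stiffness <= 0:
            raise ParameterError("contact stiffness must be positive")
        if self.damping < 0:
            raise ParameterError("damping must be non-negative")
        if self.drop_height_m <= 0 or self.hammer_mass_kg <= 0:
            raise ParameterError("drop height and hammer mass must be positive")
        if self.fine_dt > 1.0 / (10.0 * self.sensor.frame_rate):
            raise ParameterError("fine_dt must be <= one tenth of the frame period")

    @property
    def impact_velocity(self) -> float:
        return float(np.sqrt(2.0 * self.gravity * self.drop_height_m))

    @property
    def center(self) -> tuple[int, int]:
        if self.contact_center is not None:
            return self.contact_center
        return self.sensor.rows // 2, self.sensor.cols // 2


@dataclass(frozen=True)
class KinematicsTruth:
    """Fine-timestep hammer state and work bookkeeping."""

    time_s: np.ndarray
    velocity_mps: np.ndarray
    penetration_m: np.ndarray
    total_force_n: np.ndarray
    work_j: np.ndarray  # cumulative signed work done on the fruit

    @property
    def rest_index(self) -> int:
        """First fine step where the hammer velocity is <= 0 (else last)."""
        below = np.nonzero(self.velocity_mps <= 0)[0]
        return int(below[0]) if below.size else int(self.velocity_mps.size - 1)

    @property
    def work_to_rest_j(self) -> float:
        """Signed work deposited up to the hammer's first standstill."""
        return float(self.work_j[self.rest_index])

    @property
    def deposited_j(self) -> float:
        """Net signed work over the whole simulated window."""
        return float(self.work_j[-1])


@dataclass(frozen=True)
class SimulationResult:
    stack: PressureFrameStack
    truth_energy: EnergyMap
    kinematics: KinematicsTruth
    params: SimulatorParams

    def truth_energy_profile(self, axis: str = "row") -> EnergyProfile:
        r, c = self.params.center
        pitch = self.params.sensor.pitch_mm
        values = self.truth_energy.energy[r, :] if axis == "row" else self.truth_energy.energy[:, c]
        center_index = c if axis == "row" else r
        return EnergyProfile(
            positions_mm=np.arange(values.size, dtype=float) * pitch,
            energy_j=values.copy(),
            center_index=center_index,
        )

    def peak_force_profile(self, axis: str = "row") -> np.ndarray:
        r, c = self.params.center
        peak = self.stack.peak_force_map()
        return peak[r, :] if axis == "row" else peak[:, c]


def simulate_impact(p: SimulatorParams) -> SimulationResult:
    """Integrate the hammer drop and record sensor frames plus ground truth.

    Returns the frame stack at the sensor's frame rate (frame values are
    the within-frame average force per sensing point, so frame sums
    integrate to the true impulse), the fine-timestep work map as the
    ground-truth energy, and the fine kinematics history.

    Raises
    ------
    SimulationError
        If penetration exceeds ``penetration_cap_m``.
    """
    sensor = p.sensor
    dt = p.fine_dt
    z = sensor.frame_rate
    m = p.hammer_mass_kg
    cr, cc = p.center

    # grid point distances from the contact centre, in metres
    pitch_m = sensor.pitch_mm / 1000.0
    ii, jj = np.meshgrid(np.arange(sensor.rows), np.arange(sensor.cols), indexing="ij")
    r2 = ((ii - cr) ** 2 + (jj - cc) ** 2) * pitch_m**2

    n_bins = int(np.ceil(p.max_time_s * z)) + 1
    frame_acc = np.zeros((n_bins, sensor.rows, sensor.cols))
    energy_acc = np.zeros((sensor.rows, sensor.cols))

    v = p.impact_velocity  # downward positive
    delta = 0.0
    t = 0.0
    times, vels, deltas, ftots, works = [], [], [], [], []
    work = 0.0
    n_steps = int(np.ceil(p.max_time_s / dt))
    for _ in range(n_steps):
        if delta > 0:
            f_tot = p.contact_stiffness * delta**1.5 + p.damping * v
            f_tot = max(f_tot, 0.0)
        else:
            f_tot = 0.0
        times.append(t)
        vels.append(v)
        deltas.append(delta)
        ftots.append(f_tot)
        works.append(work)
        if f_tot > 0.0:
            a_contact = min(p.contact_radius_coeff * np.sqrt(delta), p.contact_radius_max_m)
            w = np.sqrt(np.clip(1.0 - r2 / a_contact**2, 0.0, None))
            s = w.sum()
            if s == 0.0:
                grid_f = np.zeros_like(w)
                grid_f[cr, cc] = f_tot
            else:
                grid_f = (f_tot / s) * w
            bin_idx = min(int(t * z), n_bins - 1)
            frame_acc[bin_idx] += grid_f * dt
            energy_acc += grid_f * (v * dt)
            work += f_tot * v * dt
        # semi-implicit Euler; gravity during contact neglected by design
        v += (-f_tot / m) * dt
        delta += v * dt
        t += dt
        if delta > p.penetration_cap_m:
            raise SimulationError(
                f"penetration {delta:.3f} m exceeded cap {p.penetration_cap_m} m"
            )
        if delta <= 0.0 and v <= 0.0 and len(times) > 1:
            break

    kin = KinematicsTruth(
        time_s=np.asarray(times),
        velocity_mps=np.asarray(vels),
        penetration_m=np.asarray(deltas),
        total_force_n=np.asarray(ftots),
        work_j=np.asarray(works),
    )
    frame_forces = frame_acc * z  # time-average over the frame period
    loaded = np.nonzero(frame_forces.sum(axis=(1, 2)) > 0)[0]
    if loaded.size == 0:
        raise SimulationError("simulation produced no contact frames")
    frame_forces = frame_forces[: loaded[-1] + 1]
    stack = PressureFrameStack(forces=frame_forces, sensor=sensor)
    truth = EnergyMap(energy=np.clip(energy_acc, 0.0, None), sensor=sensor)
    return SimulationResult(stack=stack, truth_energy=truth, kinematics=kin, params=p)


# ---------------------------------------------------------------------------
# Section image rendering


@dataclass(frozen=True)
class SectionParams:
    """Programmed geometry and appearance of a synthetic section image.

    ``depth_profile_mm`` / ``width_profile_mm`` give the band centre depth
    below the peel and the band thickness per image column (NaN depth =
    band absent).  ``gaps_px`` lists half-open column intervals where the
    band is suppressed (discontinuities).
    """

    width_px: int = 400
    height_px: int = 300
    scale_mm_per_px: float = 0.02
    peel_row_px: float = 30.0
    peel_bow_px: float = 0.0  # extra sag of the peel arc at the image edges
    depth_profile_mm: np.ndarray | None = None
    width_profile_mm: np.ndarray | None = None
    gaps_px: tuple[tuple[int, int], ...] = ()
    stain_noise: float = 0.1
    band_saturation: float = 0.85
    tissue_saturation: float = 0.15
    min_depth_mm: float = 1.2
    cell_boundary_depth_mm: float = 1.2
    small_cell_mm: float = 0.05
    large_cell_mm: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ParameterError("scale must be positive")
        if self.stain_noise < 0:
            raise ParameterError("stain noise must be non-negative")

    def peel_curve(self) -> np.ndarray:
        x = np.arange(self.width_px, dtype=float)
        cx = (self.width_px - 1) / 2.0
        half = max(cx, 1.0)
        return self.peel_row_px + self.peel_bow_px * ((x - cx) / half) ** 2

    def profiles(self) -> tuple[np.ndarray, np.ndarray]:
        if self.depth_profile_mm is None:
            d = np.full(self.width_px, 3.0)
        else:
            d = np.asarray(self.depth_profile_mm, dtype=float)
        if self.width_profile_mm is None:
            w = np.full(self.width_px, 0.8)
        else:
            w = np.asarray(self.width_profile_mm, dtype=float)
        if d.size != self.width_px or w.size != self.width_px:
            raise ParameterError("profiles must have one value per image column")
        present = ~np.isnan(d)
        if np.any(d[present] < self.min_depth_mm - 1e-9):
            raise ValidationError(
                f"band depth below the minimum of {self.min_depth_mm} mm"
            )
        if np.any(w[present] <= 0):
            raise ValidationError("band width must be positive where present")
        return d, w


@dataclass(frozen=True)
class SectionSample:
    image: SectionImage
    peel_truth: PeelCurve
    damage_truth: DamageProfile
    band_mask: np.ndarray
    params: SectionParams
    origin_mm: float = 0.0  # lateral position of image column 0 in the sensor frame


def _cell_mosaic(p: SectionParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel cell id and a wall mask from a two-density seed mosaic."""
    h, w = p.height_px, p.width_px
    peel = p.peel_curve()
    boundary_px = p.cell_boundary_depth_mm / p.scale_mm_per_px
    small_px = max(p.small_cell_mm / p.scale_mm_per_px, 1.2)
    large_px = max(p.large_cell_mm / p.scale_mm_per_px, 2.0)

    def _seeds(n: int, cell_px: float, depth_lo: float, depth_hi: float) -> np.ndarray:
        xs = rng.uniform(0, w, n)
        ys = rng.uniform(depth_lo, depth_hi, n) + np.interp(xs, np.arange(w), peel)
        return np.column_stack([ys, xs])

    max_depth = h - peel.min()
    n_small = int(w * boundary_px / small_px**2) + 1
    n_large = int(w * max(max_depth - boundary_px, 1) / large_px**2) + 1
    seeds = np.vstack(
        [
            _seeds(n_small, small_px, 0, boundary_px),
            _seeds(n_large, large_px, boundary_px, max_depth),
        ]
    )
    tree = cKDTree(seeds)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, idx = tree.query(pts, k=2, workers=1)
    cell_id = idx[:, 0].reshape(h, w)
    wall = (dist[:, 1] - dist[:, 0]).reshape(h, w) < 0.9
    return cell_id, wall


def render_section(p: SectionParams) -> SectionSample:
    """Render a stained section image and its exact ground truth.

    Raises
    ------
    ParameterError
        If the programmed band does not fit inside the image.
    """
    rng = np.random.default_rng(p.seed)
    h, w = p.height_px, p.width_px
    peel = p.peel_curve()
    depth_mm, width_mm = p.profiles()

    present = ~np.isnan(depth_mm)
    for lo, hi in p.gaps_px:
        present[lo:hi] = False
    center_px = np.where(present, peel + depth_mm / p.scale_mm_per_px, np.nan)
    half_px = np.where(present, width_mm / (2.0 * p.scale_mm_per_px), np.nan)
    if np.any(center_px[present] + half_px[present] >= h - 1):
        raise ParameterError("band extends beyond the bottom of the image")

    cell_id, wall = _cell_mosaic(p, rng)
    n_cells = int(cell_id.max()) + 1
    cell_val = 0.55 + 0.18 * rng.standard_normal(n_cells)
    cell_sat = p.tissue_saturation * (1.0 + 0.4 * rng.standard_normal(n_cells))
    # sparse section-prep cell death: a few cells stain blue
    speckle_frac = 0.02 + 0.06 * p.stain_noise
    speckle = rng.random(n_cells) < speckle_frac

    hue = np.full((h, w), 0.13)  # pale yellowish tissue
    sat = np.clip(cell_sat[cell_id], 0.02, 0.6)
    val = np.clip(cell_val[cell_id], 0.45, 0.95)
    val[wall] *= 0.85

    spk = speckle[cell_id]
    hue[spk] = 0.60
    sat[spk] = np.clip(0.55 + 0.1 * rng.standard_normal(int(spk.sum())), 0.4, 0.9)

    rows = np.arange(h)[:, None]
    band = present[None, :] & (np.abs(rows - center_px[None, :]) <= half_px[None, :])
    hue[band] = 0.60
    sat[band] = np.clip(
        p.band_saturation + 0.05 * rng.standard_normal(int(band.sum())), 0.5, 1.0
    )
    val[band] = np.clip(0.45 + 0.05 * rng.standard_normal(int(band.sum())), 0.2, 0.8)

    background = rows < peel[None, :]
    hue[background] = 0.0
    sat[background] = 0.02
    val[background] = 0.06

    noise_sd = 0.01 + 0.04 * p.stain_noise
    sat = np.clip(sat + noise_sd * rng.standard_normal((h, w)), 0.0, 1.0)
    val = np.clip(val + noise_sd * rng.standard_normal((h, w)), 0.0, 1.0)

    rgb = hsv2rgb(np.stack([hue, sat, val], axis=-1))
    image = SectionImage(rgb=rgb, scale_mm_per_px=p.scale_mm_per_px, peel_side="top")

    lateral = np.arange(w, dtype=float) * p.scale_mm_per_px
    damage_truth = DamageProfile(
        lateral_mm=lateral,
        depth_mm=np.where(present, depth_mm, 0.0),
        width_mm=np.where(present, width_mm, 0.0),
        defined=present,
    )
    return SectionSample(
        image=image,
        peel_truth=PeelCurve(y_peel=peel),
        damage_truth=damage_truth,
        band_mask=band,
        params=p,
    )


# ---------------------------------------------------------------------------
# Coupled samples: depth tracks energy, width does not


@dataclass(frozen=True)
class CoupledSampleTruth:
    """Coupling law between the energy profile and the band geometry.

    Depth at a sensing point with energy E is
    ``min_depth + alpha * E + N(0, sigma(h))`` clamped at ``min_depth_mm``,
    and the band is present only where E exceeds ``presence_rel_floor``
    times the profile peak (the yield-force analogue: weakly loaded edge
    points develop no zone).  The noise-free relation is exactly affine,
    so the pipeline Pearson r is 1 by construction.
    ``sigma(h) = sigma0 * (href / h) ** sigma_exponent`` shrinks with drop
    height.  Width is drawn independently of energy.
    """

    alpha_mm_per_j: float = 150.0
    sigma0_mm: float = 0.15
    href_m: float = 0.2
    sigma_exponent: float = 1.2
    min_depth_mm: float = 1.2
    presence_rel_floor: float = 0.12
    width_base_mm: float = 0.8
    width_jitter_mm: float = 0.3
    lateral_offset_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_mm_per_j <= 0:
            raise ParameterError("coupling coefficient must be positive")
        if self.sigma0_mm < 0:
            raise ParameterError("noise sd must be non-negative")

    def sigma_mm(self, height_m: float) -> float:
        return self.sigma0_mm * (self.href_m / height_m) ** self.sigma_exponent


@dataclass(frozen=True)
class CoupledSample:
    stack: PressureFrameStack
    truth_energy: EnergyMap
    energy_profile_truth: EnergyProfile
    damage_truth: DamageProfile
    damage_center_mm: float
    peak_force_profile: np.ndarray
    height_m: float
    yield_force_n: float
    simulation: SimulationResult
    coupling: CoupledSampleTruth
    section: SectionSample | None = None


def make_coupled_sample(
    sim_params: SimulatorParams,
    coupling: CoupledSampleTruth,
    sim: SimulationResult | None = None,
    render: bool = False,
    render_scale_mm_per_px: float = 0.05,
    yield_force_n: float | None = None,
    axis: str = "row",
    support_margin_points: int = 2,
) -> CoupledSample:
    """Build a full sample whose band depth tracks the energy profile.

    ``sim`` may carry a precomputed simulation (same parameters) so that
    Monte-Carlo sweeps over coupling seeds do not re-integrate the
    physics.  ``yield_force_n`` defaults to a quarter of the maximum
    per-point peak force — a yield analogue on the synthetic force scale.

    Raises
    ------
    ValidationError
        If the energy profile is degenerate (no point reaches the
        presence threshold).
    """
    sim = sim or simulate_impact(sim_params)
    rng = np.random.default_rng(coupling.seed)
    profile = sim.truth_energy_profile(axis=axis)
    peak_force = sim.peak_force_profile(axis=axis)
    h = sim_params.drop_height_m
    pitch = sim_params.sensor.pitch_mm

    energy = profile.energy_j
    if energy.max() <= 0:
        raise ValidationError("degenerate energy profile: no energy deposited")
    present = energy >= coupling.presence_rel_floor * energy.max()
    if present.sum() < 3:
        raise ValidationError("degenerate energy profile: band present at < 3 points")

    sigma = coupling.sigma_mm(h)
    depth = (
        coupling.min_depth_mm
        + coupling.alpha_mm_per_j * energy
        + sigma * rng.standard_normal(energy.size)
    )
    depth = np.maximum(depth, coupling.min_depth_mm)
    depth[~present] = 0.0

    width_noise = gaussian_filter1d(rng.standard_normal(energy.size), sigma=2.0)
    width = coupling.width_base_mm + coupling.width_jitter_mm * width_noise
    width = np.clip(width, 0.1, None)
    width[~present] = 0.0

    # a section image only spans the bruise neighbourhood: crop the damage
    # profile to the band support plus a small margin of zero-depth columns
    idx = np.nonzero(present)[0]
    lo = max(int(idx[0]) - support_margin_points, 0)
    hi = min(int(idx[-1]) + support_margin_points, energy.size - 1)
    window = slice(lo, hi + 1)
    lateral = profile.positions_mm + coupling.lateral_offset_mm
    damage_truth = DamageProfile(
        lateral_mm=lateral[window],
        depth_mm=depth[window],
        width_mm=width[window],
        defined=present[window],
    )
    damage_center = float(profile.center_position_mm + coupling.lateral_offset_mm)

    if yield_force_n is None:
        yield_force_n = 0.25 * float(peak_force.max())

    section = None
    if render:
        section = _render_coupled_section(
            damage_truth, pitch, render_scale_mm_per_px, coupling, rng
        )

    return CoupledSample(
        stack=sim.stack,
        truth_energy=sim.truth_energy,
        energy_profile_truth=profile,
        damage_truth=damage_truth,
        damage_center_mm=damage_center,
        peak_force_profile=peak_force,
        height_m=h,
        yield_force_n=float(yield_force_n),
        simulation=sim,
        coupling=coupling,
        section=section,
    )


def _render_coupled_section(
    damage: DamageProfile,
    pitch_mm: float,
    scale: float,
    coupling: CoupledSampleTruth,
    rng: np.random.Generator,
) -> SectionSample:
    """Rasterise the sensor-grid damage truth into a section image."""
    idx = np.nonzero(damage.defined)[0]
    lo_mm = damage.lateral_mm[idx[0]] - 2 * pitch_mm
    hi_mm = damage.lateral_mm[idx[-1]] + 2 * pitch_mm
    w_px = int(np.ceil((hi_mm - lo_mm) / scale))
    x_mm = lo_mm + np.arange(w_px) * scale
    # interpolate depth/width between sensor points; absent outside support
    d = np.interp(x_mm, damage.lateral_mm[idx], damage.depth_mm[idx])
    wdt = np.interp(x_mm, damage.lateral_mm[idx], damage.width_mm[idx])
    inside = (x_mm >= damage.lateral_mm[idx[0]]) & (x_mm <= damage.lateral_mm[idx[-1]])
    d = np.where(inside, np.maximum(d, coupling.min_depth_mm), np.nan)
    peel_row = 25.0
    h_px = int(peel_row + (np.nanmax(d) + np.nanmax(wdt) + 2.0) / scale) + 10
    params = SectionParams(
        width_px=w_px,
        height_px=h_px,
        scale_mm_per_px=scale,
        peel_row_px=peel_row,
        depth_profile_mm=d,
        width_profile_mm=np.where(inside, wdt, 1.0),
        stain_noise=0.1,
        min_depth_mm=coupling.min_depth_mm,
        seed=int(rng.integers(0, 2**31)),
    )
    return replace(render_section(params), origin_mm=float(lo_mm))


def write_coupled_sample(sample: CoupledSample, out_dir: str | os.PathLike) -> None:
    """Emit the on-disk form of a sample: frames, optional image, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_frame_stack(sample.stack, out / "frames.csv")
    if sample.section is not None:
        write_section(sample.section.image, out / "section.tiff")
    truth = {
        "height_m": sample.height_m,
        "damage_center_mm": sample.damage_center_mm,
        "yield_force_n": sample.yield_force_n,
        "coupling_seed": sample.coupling.seed,
        "alpha_mm_per_j": sample.coupling.alpha_mm_per_j,
        "sigma_mm": sample.coupling.sigma_mm(sample.height_m),
        "energy_profile_j": sample.energy_profile_truth.energy_j.tolist(),
        "energy_center_index": sample.energy_profile_truth.center_index,
        "depth_truth_mm": sample.damage_truth.depth_mm.tolist(),
        "width_truth_mm": sample.damage_truth.width_mm.tolist(),
        "defined": sample.damage_truth.defined.astype(int).tolist(),
        "peak_force_n": sample.peak_force_profile.tolist(),
    }
    if sample.section is not None:
        truth["image_origin_mm"] = sample.section.origin_mm
        truth["image_damage_center_mm"] = (
            sample.damage_center_mm - sample.section.origin_mm
        )
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def rest_impact_params(
    drop_height_m: float,
    frame_rate: float = 60.0,
    fine_dt: float = 1e-5,
    seed: int = 0,
) -> SimulatorParams:
    """Heavily damped parameters that bring the hammer to rest in contact.

    Used by the energy-accounting checks: essentially all of the kinetic
    energy ``m g h`` is deposited because the hammer never rebounds.
    """
    return SimulatorParams(
        drop_height_m=drop_height_m,
        contact_stiffness=30.0,
        damping=6.0,
        fine_dt=fine_dt,
        sensor=SensorSpec(frame_rate=frame_rate),
        max_time_s=1.5,
        seed=seed,
    )
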