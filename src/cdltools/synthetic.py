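"""Parametric cochlea phantoms with known ground truth.

A simple spiral family stands in for cadaver anatomy: the lateral-wall
radius decays linearly with the winding angle, an optional elliptic
modulation deforms the basal turn (blended out after 360 deg), and the
axial rise is piecewise linear with a steeper apical pitch. Defaults are
calibrated so one specimen lands in the anatomically reported ranges -
full lateral-wall CDL in the high 30s to mid 40s of mm, A-value around
8.5-10.5 mm, height around 4 mm, 2.5 turns - without claiming anatomical
fidelity beyond those summary dimensions.

The module also rasterises a curve into a CT-like voxel phantom (fluid
lumen, bone shell, air background with HU-like intensities), segments it
back by thresholding, and simulates per-method/per-rater measurement
tables with additive bias and Gaussian noise - the data supply for the
pipeline's end-to-end tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .geometry import LateralWallPointCloud

__all__ = [
    "GenerationError",
    "SegmentationError",
    "SpiralParams",
    "SpiralCurve",
    "GroundTruth",
    "VoxelPhantom",
    "ErrorModel",
    "MEASUREMENT_METHODS",
    "make_spiral",
    "sample_point_cloud",
    "rasterize_to_volume",
    "threshold_segment",
    "simulate_measurements",
    "generate_cohort",
    "Cohort",
]


class GenerationError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


#: method labels of the measurement table (modality crossed into the label)
MEASUREMENT_METHODS = ("3D-HRCT", "3D-CBCT", "A-HRCT", "A-CBCT",
                       "SW-HRCT", "SW-CBCT", "reference")


@dataclass(frozen=True)
class SpiralParams:
    """Parameters of the spiral lateral-wall family.

    r0 : basal lateral-wall radius (mm).
    decay_per_deg : linear per-degree radial shrink; radius is
        ``r0 * (1 - decay_per_deg * theta)``.
    pitch_basal / pitch_apical : axial rise (mm per degree) before/after
        ``pitch_break_deg`` - apical turns climb faster, as in anatomy.
    turns_deg : total winding extent (900 deg = 2.5 turns).
    ellipticity : relative cos(2*theta) radial modulation of the basal
        turn, linearly blended out by 360 deg.
    """

    r0: float = 4.7
    decay_per_deg: float = 0.00095
    pitch_basal: float = 1.0 / 360.0
    pitch_apical: float = 3.0 / 540.0
    pitch_break_deg: float = 360.0
    turns_deg: float = 900.0
    ellipticity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise GenerationError("r0 must be positive")
        if not 90.0 <= self.turns_deg <= 990.0:
            raise GenerationError("turns_deg must lie in [90, 990]")
        if self.turns_deg < 720.0:
            # anatomically a cochlea has 2-2.75 turns; shorter extents are
            # allowed for calibration curves (circles, partial arcs)
            warnings.warn("turns_deg < 720: not an anatomical cochlea",
                          stacklevel=2)
        r_end = self.r0 * (1.0 - self.decay_per_deg * self.turns_deg)
        if r_end <= 0.05:
            raise GenerationError("radius collapses before the apex "
                                  "(self-intersecting parameters)")


class SpiralCurve:
    """Continuous lateral-wall curve of a :class:`SpiralParams` spiral."""

    def __init__(self, params: SpiralParams) -> None:
        self.params = params

    def radius(self, theta_deg):
        p = self.params
        theta_deg = np.asarray(theta_deg, dtype=float)
        base = p.r0 * (1.0 - p.decay_per_deg * theta_deg)
        if p.ellipticity:
            blend = np.clip(1.0 - theta_deg / 360.0, 0.0, 1.0)
            base = base * (1.0 + p.ellipticity * blend
                           * np.cos(2.0 * np.radians(theta_deg)))
        return base

    def height(self, theta_deg):
        p = self.params
        theta_deg = np.asarray(theta_deg, dtype=float)
        basal = np.minimum(theta_deg, p.pitch_break_deg) * p.pitch_basal
        apical = np.maximum(theta_deg - p.pitch_break_deg, 0.0) * p.pitch_apical
        return basal + apical

    def point(self, theta_deg) -> np.ndarray:
        theta_deg = np.asarray(theta_deg, dtype=float)
        r = self.radius(theta_deg)
        th = np.radians(theta_deg)
        return np.stack([r * np.cos(th), r * np.sin(th),
                         self.height(theta_deg)], axis=-1)

    def speed(self, theta_deg) -> np.ndarray:
        """|dC/d theta| in mm per degree (central differences, h = 1e-3 deg)."""
        h = 1e-3
        theta_deg = np.asarray(theta_deg, dtype=float)
        d = (self.point(theta_deg + h) - self.point(theta_deg - h)) / (2 * h)
        return np.linalg.norm(d, axis=-1)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic/numeric ground truth of one spiral specimen.

    ``full_cdl_mm`` integrates the lateral-wall speed at ``step_deg``
    resolution (composite Simpson); A/B are the axis chords evaluated on
    the continuous radius, H the total axial rise.
    """

    curve: SpiralCurve
    full_cdl_mm: float
    A_mm: float
    B_mm: float
    H_mm: float
    step_deg: float = 0.01
    _theta_grid: np.ndarray = field(repr=False, default=None)
    _cdl_grid: np.ndarray = field(repr=False, default=None)

    def cdl_lw(self, theta_deg) -> np.ndarray:
        """Cumulative lateral-wall length from the RW to theta (mm)."""
        return np.interp(theta_deg, self._theta_grid, self._cdl_grid)


def make_spiral(params: SpiralParams = SpiralParams(),
                step_deg: float = 0.01) -> tuple[SpiralCurve, GroundTruth]:
    """Build a continuous spiral and its integration ground truth."""
    curve = SpiralCurve(params)
    n = int(np.ceil(params.turns_deg / step_deg))
    if n % 2:  # Simpson wants an even interval count
        n += 1
    theta = np.linspace(0.0, params.turns_deg, n + 1)
    cum = cumulative_simpson(curve.speed(theta), x=theta, initial=0.0)
    gt = GroundTruth(
        curve=curve,
        full_cdl_mm=float(cum[-1]),
        A_mm=float(curve.radius(0.0) + curve.radius(180.0)),
        B_mm=float(curve.radius(90.0) + curve.radius(270.0)),
        H_mm=float(curve.height(params.turns_deg) - curve.height(0.0)),
        step_deg=step_deg,
        _theta_grid=theta,
        _cdl_grid=cum,
    )
    return curve, gt


def sample_point_cloud(curve: SpiralCurve, n: int = 500,
                       noise_sd: float = 0.0,
                       seed: int | np.random.Generator = 0,
                       side: str = "right") -> LateralWallPointCloud:
    """Sample n lateral-wall points at uniform angular spacing.

    Isotropic Gaussian jitter of ``noise_sd`` mm per axis emulates rater
    click scatter; point 0 is the round window (theta = 0).
    """
    if n < 4:
        raise GenerationError("need at least 4 points")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, curve.params.turns_deg, n)
    pts = curve.point(theta)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return LateralWallPointCloud(pts, rw_index=0, side=side)


@dataclass(frozen=True)
class VoxelPhantom:
    """CT-like intensity volume (HU-like integers).

    ``origin_mm`` is the position of voxel (0, 0, 0)'s center; data axes
    are (x, y, z).
    """

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    fluid_value: int = 0
    bone_value: int = 700
    background_value: int = -1000

    def voxel_centers(self, index_array: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(index_array, float) * self.spacing_mm


def default_lumen_profile(turns_deg: float,
                          basal_mm: float = 0.6,
                          apical_mm: float = 0.25) -> Callable:
    """Duct (scala) radius tapering linearly from base to apex.

    The apical radius is kept below half the apical wall radius so the
    duct never crosses the modiolar axis (an axis-crossing lumen has no
    well-defined lateral wall in the projection used for extraction).
    """
    def profile(theta_deg):
        f = np.clip(np.asarray(theta_deg, float) / turns_deg, 0.0, 1.0)
        return basal_mm + (apical_mm - basal_mm) * f
    return profile


def rasterize_to_volume(curve: SpiralCurve,
                        lumen_radius_profile: Optional[Callable] = None,
                        spacing: float = 0.2,
                        shell_mm: float = 0.5,
                        margin_mm: float = 1.5,
                        fluid_value: int = 0,
                        bone_value: int = 700,
                        background_value: int = -1000,
                        inset_by_lumen: bool = True,
                        max_voxels: int = 300_000_000) -> VoxelPhantom:
    """Voxelise the duct as fluid tube + bone shell in an air background.

    With ``inset_by_lumen`` (default) the duct-center curve is the lateral
    wall inset radially (in xy) by the local lumen radius, so the outer
    surface of the fluid tube traces the lateral wall; without it the
    curve itself is the tube center (calibration tubes). Voxels within
    the lumen radius of the center curve are fluid, within
    ``lumen + shell_mm`` bone, elsewhere background.
    """
    if not 0.05 <= spacing <= 0.5:
        raise ValueError("spacing must be in [0.05, 0.5] mm")
    turns = curve.params.turns_deg
    if lumen_radius_profile is None:
        lumen_radius_profile = default_lumen_profile(turns)

    theta = np.arange(0.0, turns + 0.25, 0.25)
    wall = curve.point(theta)
    lumen = np.asarray(lumen_radius_profile(theta), dtype=float)
    if np.ndim(lumen) == 0:
        lumen = np.full(len(theta), float(lumen))
    centers = wall.copy()
    if inset_by_lumen:
        rho = np.maximum(np.hypot(wall[:, 0], wall[:, 1]), 1e-9)
        scale = np.clip((rho - lumen) / rho, 0.02 / rho, None)
        centers[:, 0] *= scale
        centers[:, 1] *= scale

    pad = lumen.max() + shell_mm + margin_mm
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"phantom would need {np.prod(shape):.2e} voxels; increase spacing")

    axes = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(centers)
    dist, idx = tree.query(grid, workers=-1)
    local_lumen = lumen[idx]
    data = np.full(shape, background_value, dtype=np.int16)
    flat = data.reshape(-1)
    flat[dist <= local_lumen + shell_mm] = bone_value
    flat[dist <= local_lumen] = fluid_value
    return VoxelPhantom(data=data, spacing_mm=spacing, origin_mm=lo,
                        fluid_value=fluid_value, bone_value=bone_value,
                        background_value=background_value)


def threshold_segment(phantom: VoxelPhantom,
                      lo: float = -1024.0, hi: float = 280.0,
                      select_lumen: bool = False) -> np.ndarray:
    """Threshold the volume and export boundary voxel centers (mm).

    The mask keeps voxels with intensity in [lo, hi] (defaults follow the
    HRCT fluid window). ``select_lumen`` emulates the manual "region A"
    step of a clinical workflow: connected components touching the volume
    border (the air background) are dropped and the largest remaining
    component is kept. Boundary voxels are mask voxels with at least one
    non-mask 6-neighbor; they are returned at their voxel centers - a
    deliberate voxel-quantised stand-in for points clicked on the wall.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    mask = (phantom.data >= lo) & (phantom.data <= hi)
    if not mask.any():
        raise SegmentationError("empty mask: no voxels in threshold window")
    if select_lumen:
        labels = cc_label(mask, connectivity=1)
        border = np.unique(np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        counts[border] = 0
        if counts.max() == 0:
            raise SegmentationError("no interior component in threshold window")
        mask = labels == int(counts.argmax())
    interior = mask.copy()
    inner = interior[1:-1, 1:-1, 1:-1]
    inner &= mask[:-2, 1:-1, 1:-1] & mask[2:, 1:-1, 1:-1]
    inner &= mask[1:-1, :-2, 1:-1] & mask[1:-1, 2:, 1:-1]
    inner &= mask[1:-1, 1:-1, :-2] & mask[1:-1, 1:-1, 2:]
    interior[1:-1, 1:-1, 1:-1] = inner
    interior[[0, -1], :, :] = False
    interior[:, [0, -1], :] = False
    interior[:, :, [0, -1]] = False
    boundary = mask & ~interior
    return phantom.voxel_centers(np.argwhere(boundary))


@dataclass(frozen=True)
class ErrorModel:
    """Additive measurement-error model per method plus rater jitter.

    ``cdl_bias_mm[method]`` shifts that method's CDL observation (negative
    = underestimation relative to truth); ``cdl_noise_sd_mm[method]`` is
    the per-observation Gaussian sd; ``landmark_jitter_sd_mm`` jitters the
    A/B/H landmark observations per rater. Defaults emulate the
    underestimation pattern reported for clinical CT workflows.
    """

    cdl_bias_mm: dict = field(default_factory=lambda: {
        "3D-HRCT": -7.7, "3D-CBCT": -6.2, "A-HRCT": -7.2, "A-CBCT": -5.0,
        "SW-HRCT": -6.2, "SW-CBCT": -5.6, "reference": 0.0})
    cdl_noise_sd_mm: dict = field(default_factory=lambda: {
        "3D-HRCT": 1.0, "3D-CBCT": 1.0, "A-HRCT": 1.0, "A-CBCT": 1.0,
        "SW-HRCT": 1.0, "SW-CBCT": 1.0, "reference": 0.8})
    landmark_jitter_sd_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.cdl_noise_sd_mm.values()):
            raise ValueError("noise sds must be non-negative")
        if self.landmark_jitter_sd_mm < 0:
            raise ValueError("jitter sd must be non-negative")


def simulate_measurements(truth: GroundTruth,
                          model: ErrorModel = ErrorModel(),
                          raters: int = 2,
                          specimen_id: str = "S01",
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Long-format measurement rows for one specimen.

    One row per (method, rater): CDL observation = truth + method bias +
    Gaussian noise; landmark observations = truth + rater jitter.
    """
    if raters < 1:
        raise ValueError("need at least one rater")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    rows = []
    for rater in range(1, raters + 1):
        for method in MEASUREMENT_METHODS:
            sd = model.cdl_noise_sd_mm.get(method, 0.0)
            cdl = (truth.full_cdl_mm + model.cdl_bias_mm.get(method, 0.0)
                   + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            jit = model.landmark_jitter_sd_mm
            jitter = rng.normal(0.0, jit, 3) if jit > 0 else np.zeros(3)
            rows.append({
                "specimen_id": specimen_id,
                "method": method,
                "rater_id": f"R{rater}",
                "cdl_mm": cdl,
                "A_mm": truth.A_mm + jitter[0],
                "B_mm": truth.B_mm + jitter[1],
                "H_mm": truth.H_mm + jitter[2],
            })
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A reproducible synthetic cohort exercising the whole pipeline."""

    params: list
    curves: list
    truths: list
    clouds: list
    table: pd.DataFrame
    phantoms: list = field(default_factory=list)


def generate_cohort(n_specimens: int = 20,
                    base_params: SpiralParams = SpiralParams(),
                    error_model: ErrorModel = ErrorModel(),
                    seed: int = 0,
                    raters: int = 2,
                    n_points: int = 500,
                    cloud_noise_sd: float = 0.1,
                    r0_sd: float = 0.45,
                    height_sd: float = 0.3,
                    with_phantoms: bool = False,
                    phantom_spacing: float = 0.2) -> Cohort:
    """Generate a cohort of spiral specimens with clouds and measurements.

    Specimen anatomy varies through the basal radius (lognormal-free
    truncated normal around ``base_params.r0``) and total height; the
    measurement table applies the cohort's error model per method/rater.
    Fully deterministic for a given seed.
    """
    if n_specimens < 2:
        raise ValueError("cohort needs at least 2 specimens")
    rng = np.random.default_rng(seed)
    params_list, curves, truths, clouds, phantoms = [], [], [], [], []
    tables = []
    for i in range(n_specimens):
        r0 = float(np.clip(rng.normal(base_params.r0, r0_sd), 3.8, 5.6))
        h = float(np.clip(rng.normal(4.0, height_sd), 3.0, 5.0))
        p = SpiralParams(
            r0=r0,
            decay_per_deg=base_params.decay_per_deg,
            pitch_basal=0.25 * h / base_params.pitch_break_deg,
            pitch_apical=0.75 * h / (base_params.turns_deg
                                     - base_params.pitch_break_deg),
            pitch_break_deg=base_params.pitch_break_deg,
            turns_deg=base_params.turns_deg,
            ellipticity=base_params.ellipticity,
            seed=seed + i,
        )
        curve, gt = make_spiral(p)
        sid = f"S{i + 1:02d}"
        params_list.append(p)
        curves.append(curve)
        truths.append(gt)
        clouds.append(sample_point_cloud(curve, n=n_points,
                                         noise_sd=cloud_noise_sd, seed=rng))
        tables.append(simulate_measurements(gt, error_model, raters=raters,
                                            specimen_id=sid, rng=rng))
        if with_phantoms:
            phantoms.append(rasterize_to_volume(curve,
                                                spacing=phantom_spacing))
    return Cohort(params=params_list, curves=curves, truths=truths,
                  clouds=clouds, table=pd.concat(tables, ignore_index=True),
                  phantoms=phantoms)
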