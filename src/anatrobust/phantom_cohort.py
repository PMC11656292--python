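"""Synthetic longitudinal head-and-neck phantoms.

Each patient is an idealized nasopharynx anatomy on a regular voxel grid of
relative stopping power (air ~ 0.001, soft tissue 1.0, bone 1.4) with a
structure set (high-/low-risk CTV, parotids, submandibular glands, pharyngeal
constrictors, oral cavity, brainstem, spinal cord, optic chiasm, thyroid) and
six weekly verification anatomies at fractions 5, 10, ..., 30.

Interfractional change is modelled as one smooth, invertible deformation
family evaluated at each week: per-organ contraction/translation fields with
compact support (tumor and nodal shrinkage, parotid medial shift), a lateral
neck-contraction field emulating weight loss, and an optional random smooth
vector field for small nonrigid variations.  Organ volume-loss rates and
shift magnitudes default to published cohort statistics for advanced
nasopharyngeal carcinoma (parotid volume loss 28.6% +- 14.6% over the course,
CTV volume loss of 1.5%/2.3%/0.3% per treatment day for primary / nodal /
elective volumes, 2.0-2.6 mm medial parotid shift, CTV displacements of
2.5-3.7 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import (
    DisplacementField,
    GridSpec,
    StructureSet,
    VoxelGrid,
    invert_dvf,
)

RSP_AIR = 0.001
RSP_SOFT = 1.0
RSP_BONE = 1.4

DEFAULT_GRID = GridSpec(shape=(64, 64, 48), spacing=(3.0, 3.0, 3.0))

WEEKS = (1, 2, 3, 4, 5, 6)
WEEK_FRACTIONS = (5, 10, 15, 20, 25, 30)
COURSE_DAYS = 30  # treatment days at the last verification anatomy

_LOSS_FIELDS = (
    "ctv_high_loss_per_day",
    "ctv_node_loss_per_day",
    "ctv_elective_loss_per_day",
)


@dataclass(frozen=True)
class ProgressionParams:
    """Per-patient anatomical-progression parameters.

    Loss rates are fractional volume loss per treatment day; total losses are
    fractions of the planning volume reached at treatment day 30; shifts are
    total centroid displacements (mm) reached at day 30.
    """

    ctv_high_loss_per_day: float = 0.015
    ctv_node_loss_per_day: float = 0.023
    ctv_elective_loss_per_day: float = 0.003
    ctv_high_shift_mm: float = 2.5
    ctv_node_shift_mm: float = 3.2
    ctv_elective_shift_mm: float = 3.5
    parotid_total_loss: float = 0.286
    parotid_medial_shift: float = 2.3
    submandibular_total_loss: float = 0.266
    submandibular_medial_shift: float = 0.3
    thyroid_total_loss: float = 0.123
    neck_contraction: float = 3.0
    snrv_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in _LOSS_FIELDS:
            rate = getattr(self, name)
            if not 0.0 <= rate * COURSE_DAYS < 1.0:
                raise ValueError(
                    f"{name}={rate} implies course loss >= 1 (or < 0)")
        for name in ("parotid_total_loss", "submandibular_total_loss",
                     "thyroid_total_loss"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("ctv_high_shift_mm", "ctv_node_shift_mm",
                     "ctv_elective_shift_mm", "parotid_medial_shift",
                     "submandibular_medial_shift", "neck_contraction",
                     "snrv_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PatientTimeline:
    """Planning anatomy, six weekly anatomies and ground-truth forward DVFs.

    ``true_dvfs[w-1]`` maps the planning frame to the week-``w`` frame: tissue
    at planning position ``x`` sits at ``x + u(x)`` in week ``w``.
    """

    planning: VoxelGrid
    planning_structures: StructureSet
    weekly: list[tuple[VoxelGrid, StructureSet]]
    true_dvfs: list[DisplacementField]
    params: ProgressionParams

    @property
    def grid(self) -> GridSpec:
        return self.planning.grid


# --------------------------------------------------------------------------
# anatomy layout
# --------------------------------------------------------------------------

def _ellipsoid(x, y, z, center, semi):
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def _cylinder(x, y, z, center_xy, radius, z_lo, z_hi):
    return ((((x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2)
             <= radius ** 2) & (z >= z_lo) & (z <= z_hi))


def _box(x, y, z, x_half, y_lo, y_hi, z_lo, z_hi):
    return ((np.abs(x) <= x_half) & (y >= y_lo) & (y <= y_hi)
            & (z >= z_lo) & (z <= z_hi))


# Organ geometry in mm relative to the axial grid center (+x patient-left,
# +y posterior, +z superior).  Sized to the default 64x64x48 @ 3 mm frame.
_BODY_SEMI = (75.0, 80.0)
_PAROTID_CENTER = (54.0, 18.0, 8.0)
_PAROTID_SEMI = (11.0, 15.0, 19.0)
_NODE_CENTER = (28.0, 10.0, -2.0)
_NODE_SEMI = (8.0, 10.0, 12.0)
_SUBMAND_CENTER = (22.0, -18.0, -18.0)
_SUBMAND_SEMI = (9.0, 11.0, 9.0)
_THYROID_CENTER = (14.0, -20.0, -52.0)
_THYROID_SEMI = (8.0, 7.0, 10.0)
_ELECTIVE_CENTER = (0.0, 15.0, -35.0)
_CTV_HIGH_CENTER = (0.0, 10.0, 20.0)
_CTV_HIGH_RADIUS = 20.0
_CORD_XY = (0.0, 40.0)


def _implicit_masks(x, y, z, grid: GridSpec) -> dict[str, np.ndarray]:
    """Evaluate the analytic anatomy at (possibly warped) coordinates.

    Coordinates are in mm relative to the grid center.  Evaluating the same
    implicit shapes at deformed coordinates yields the deformed masks at
    sub-voxel accuracy; the result agrees with nearest-neighbour propagation
    of the planning masks up to voxelization of the boundary.
    """
    body = ((x / _BODY_SEMI[0]) ** 2 + (y / _BODY_SEMI[1]) ** 2) <= 1.0

    masks: dict[str, np.ndarray] = {"body": body}

    primary = _ellipsoid(x, y, z, _CTV_HIGH_CENTER, (_CTV_HIGH_RADIUS,) * 3)
    node_l = _ellipsoid(x, y, z, _NODE_CENTER, _NODE_SEMI)
    node_r = _ellipsoid(x, y, z, (-_NODE_CENTER[0],) + _NODE_CENTER[1:],
                        _NODE_SEMI)
    masks["ctv_high"] = primary | node_l | node_r

    elect_l = _ellipsoid(x, y, z, (33.0, 15.0, -35.0), (13.0, 22.0, 30.0))
    elect_r = _ellipsoid(x, y, z, (-33.0, 15.0, -35.0), (13.0, 22.0, 30.0))
    elect_band = _box(x, y, z, 33.0, 5.0, 30.0, -60.0, -15.0)
    margin = 3.0
    high_margin = (
        _ellipsoid(x, y, z, _CTV_HIGH_CENTER, (_CTV_HIGH_RADIUS + margin,) * 3)
        | _ellipsoid(x, y, z, _NODE_CENTER,
                     tuple(s + margin for s in _NODE_SEMI))
        | _ellipsoid(x, y, z, (-_NODE_CENTER[0],) + _NODE_CENTER[1:],
                     tuple(s + margin for s in _NODE_SEMI)))
    masks["ctv_low"] = (elect_l | elect_r | elect_band) & ~high_margin

    masks["parotid_l"] = _ellipsoid(x, y, z, _PAROTID_CENTER, _PAROTID_SEMI)
    masks["parotid_r"] = _ellipsoid(
        x, y, z, (-_PAROTID_CENTER[0],) + _PAROTID_CENTER[1:], _PAROTID_SEMI)
    masks["submandibular"] = (
        _ellipsoid(x, y, z, _SUBMAND_CENTER, _SUBMAND_SEMI)
        | _ellipsoid(x, y, z, (-_SUBMAND_CENTER[0],) + _SUBMAND_CENTER[1:],
                     _SUBMAND_SEMI))
    masks["thyroid"] = (
        _ellipsoid(x, y, z, _THYROID_CENTER, _THYROID_SEMI)
        | _ellipsoid(x, y, z, (-_THYROID_CENTER[0],) + _THYROID_CENTER[1:],
                     _THYROID_SEMI))
    masks["oral_cavity"] = _ellipsoid(x, y, z, (0.0, -32.0, 2.0),
                                      (24.0, 18.0, 16.0))
    masks["pcm_superior"] = _box(x, y, z, 14.0, 24.0, 31.0, 8.0, 22.0)
    masks["pcm_medius"] = _box(x, y, z, 14.0, 24.0, 31.0, -12.0, 8.0)
    masks["pcm_inferior"] = _box(x, y, z, 14.0, 24.0, 31.0, -32.0, -12.0)
    z_floor = -grid.extent_mm[2] / 2.0 + 1.2 * grid.spacing[2]
    masks["brainstem"] = _cylinder(x, y, z, _CORD_XY, 7.0, 15.0, 55.0)
    masks["spinal_cord"] = _cylinder(x, y, z, _CORD_XY, 4.5, z_floor, 15.0)
    masks["optic"] = _ellipsoid(x, y, z, (0.0, 5.0, 53.0), (12.0, 6.0, 4.0))

    for name, m in masks.items():
        if name != "body":
            masks[name] = m & body
    return masks


def _implicit_rsp(x, y, z, masks: dict[str, np.ndarray]) -> np.ndarray:
    """RSP phantom: soft-tissue body in air, vertebral bone around the cord."""
    body = masks["body"]
    bone = _cylinder(x, y, z, _CORD_XY, 9.5, -1e9, 55.0) & body
    bone &= ~(_cylinder(x, y, z, _CORD_XY, 6.5, -1e9, 15.0)
              | _cylinder(x, y, z, _CORD_XY, 9.0, 15.0, 55.0))
    rsp = np.full(x.shape, RSP_AIR)
    rsp[body] = RSP_SOFT
    rsp[bone] = RSP_BONE
    return rsp


def _centered_coords(grid: GridSpec):
    cx, cy, cz = grid.coordinate_grids()
    center = grid.origin_arr + grid.extent_mm / 2.0
    return cx - center[0], cy - center[1], cz - center[2]


def build_planning_anatomy(grid: GridSpec = DEFAULT_GRID
                           ) -> tuple[VoxelGrid, StructureSet]:
    """Construct the planning RSP grid and structure set on ``grid``."""
    x, y, z = _centered_coords(grid)
    masks = _implicit_masks(x, y, z, grid)
    rsp = _implicit_rsp(x, y, z, masks)
    _check_structures_inside(masks, grid)
    return VoxelGrid(rsp, grid), StructureSet(masks, grid)


def _check_structures_inside(masks: dict[str, np.ndarray], grid: GridSpec):
    interior = np.zeros(grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    for name, m in masks.items():
        if name == "body":
            continue
        if not m.any():
            raise ValueError(
                f"grid {grid.shape} too small: structure {name!r} is empty")
        if (m & ~interior).any():
            raise ValueError(
                f"grid {grid.shape} too small: {name!r} touches the boundary")


# --------------------------------------------------------------------------
# deformation family
# --------------------------------------------------------------------------

def _smoothstep_taper(r: np.ndarray, plateau: float, outer: float
                      ) -> np.ndarray:
    """1 inside ``plateau``, smooth cubic decay to 0 at ``outer``."""
    t = np.clip((r - plateau) / max(outer - plateau, 1e-9), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def _organ_pull_field(x, y, z, center, r_organ, scale, shift,
                      plateau_factor=1.15, outer_factor=2.0):
    """Week->planning displacement realizing an organ scale + translation.

    Inside the plateau the map is exactly ``psi(y) = c + (y - c - t)/lam``,
    so the weekly organ is the planning organ scaled by ``lam`` about its
    centroid and translated by ``t``; the field tapers smoothly to zero.
    """
    t = np.asarray(shift, dtype=float)
    dx = x - (center[0] + t[0])
    dy = y - (center[1] + t[1])
    dz = z - (center[2] + t[2])
    r = np.sqrt(dx * dx + dy * dy + dz * dz) / r_organ
    w = _smoothstep_taper(r, plateau_factor * scale, outer_factor)
    fac = (1.0 / scale - 1.0)
    # saturate the radial (contraction) term at the plateau edge so distant
    # structures see only the decaying tail, not a still-growing pull
    r_plateau = plateau_factor * scale
    sat = np.minimum(1.0, r_plateau / np.maximum(r, 1e-9))
    v = np.empty((3,) + x.shape)
    v[0] = w * (fac * sat * dx - t[0])
    v[1] = w * (fac * sat * dy - t[1])
    v[2] = w * (fac * sat * dz - t[2])
    return v


def _loss_to_scale(loss: float) -> float:
    loss = min(max(loss, 0.0), 0.95)
    return (1.0 - loss) ** (1.0 / 3.0)


def _week_pull_field(grid: GridSpec, params: ProgressionParams, week: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Analytic week->planning displacement field (mm) for one week."""
    x, y, z = _centered_coords(grid)
    days = float(WEEK_FRACTIONS[week - 1])
    frac = days / COURSE_DAYS

    v = np.zeros((3,) + grid.shape)

    def organ(center_mm, r_organ, loss, shift_vec, **kw):
        nonlocal v
        v += _organ_pull_field(x, y, z, center_mm, r_organ,
                               _loss_to_scale(loss),
                               np.asarray(shift_vec) * frac, **kw)

    # primary tumor: shrink + posterior-inferior drift
    organ(_CTV_HIGH_CENTER, _CTV_HIGH_RADIUS,
          params.ctv_high_loss_per_day * days,
          np.array([0.0, 0.707, -0.707]) * params.ctv_high_shift_mm)
    # nodal volumes: strong shrink + medial-posterior drift; a wide taper
    # keeps the local compression mild so the field stays well invertible.
    for s in (+1, -1):
        organ((s * _NODE_CENTER[0],) + _NODE_CENTER[1:], max(_NODE_SEMI),
              params.ctv_node_loss_per_day * days,
              np.array([-0.6 * s, 0.6, -0.53]) * params.ctv_node_shift_mm,
              outer_factor=2.6)
    # elective volume: slight shrink, mostly-posterior drift (neck flexion
    # and nodal-level settling); the plateau covers the whole collar so the
    # drift acts as a coherent translation of the nodal region
    organ(_ELECTIVE_CENTER, 60.0,
          params.ctv_elective_loss_per_day * days,
          np.array([0.0, 0.8, -0.6]) * params.ctv_elective_shift_mm,
          plateau_factor=0.95, outer_factor=1.45)
    # parotids: shrink + medial shift
    for s in (+1, -1):
        organ((s * _PAROTID_CENTER[0],) + _PAROTID_CENTER[1:],
              max(_PAROTID_SEMI), params.parotid_total_loss,
              np.array([-s, 0.0, 0.0]) * params.parotid_medial_shift)
    # submandibular glands: shrink + small medial shift
    for s in (+1, -1):
        organ((s * _SUBMAND_CENTER[0],) + _SUBMAND_CENTER[1:],
              max(_SUBMAND_SEMI), params.submandibular_total_loss,
              np.array([-s, 0.0, 0.0]) * params.submandibular_medial_shift)
    # thyroid: shrink only
    for s in (+1, -1):
        organ((s * _THYROID_CENTER[0],) + _THYROID_CENTER[1:],
              max(_THYROID_SEMI), params.thyroid_total_loss, (0, 0, 0))

    # neck contraction: weekly outline is pulled inward, so the pull-back
    # field points outward, strongest at the surface, confined to the neck.
    if params.neck_contraction > 0:
        r_norm = np.sqrt((x / _BODY_SEMI[0]) ** 2 + (y / _BODY_SEMI[1]) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            nx = np.where(r_norm > 1e-6, x / np.maximum(r_norm, 1e-6), 0.0)
            ny = np.where(r_norm > 1e-6, y / np.maximum(r_norm, 1e-6), 0.0)
        axial = _smoothstep_taper(z, 10.0, 25.0)  # neck below the head
        mag = params.neck_contraction * frac * np.clip(r_norm, 0, 1) ** 2 * axial
        v[0] += mag * nx / np.maximum(_BODY_SEMI[0], 1)
        v[1] += mag * ny / np.maximum(_BODY_SEMI[1], 1)

    # small nonrigid variations: zero-mean smooth random field, one
    # independent draw per week (trendless by definition).
    if params.snrv_sigma > 0:
        noise = rng.standard_normal((3,) + grid.shape)
        sig_vox = 12.0 / grid.spacing_arr
        for c in range(3):
            noise[c] = ndimage.gaussian_filter(noise[c], sig_vox)
        rms = np.sqrt((noise ** 2).sum(axis=0).mean())
        v += noise * (params.snrv_sigma / max(rms, 1e-12))

    return v


# --------------------------------------------------------------------------
# patient / cohort generation
# --------------------------------------------------------------------------

def make_patient(params: ProgressionParams,
                 grid: GridSpec = DEFAULT_GRID) -> PatientTimeline:
    """Generate one longitudinal patient on ``grid``.

    Weekly images and masks are produced by pulling the planning anatomy back
    through the analytic week->planning field; the stored ground-truth DVFs
    are the numerically inverted (planning->week) fields.
    """
    planning, structures = build_planning_anatomy(grid)
    rng = np.random.default_rng(params.seed)
    x, y, z = _centered_coords(grid)

    weekly: list[tuple[VoxelGrid, StructureSet]] = []
    true_dvfs: list[DisplacementField] = []
    static = _is_static(params)
    for week in WEEKS:
        if static:
            weekly.append((planning.copy(), structures.copy()))
            true_dvfs.append(DisplacementField.zeros(grid))
            continue
        v = DisplacementField(_week_pull_field(grid, params, week, rng), grid)
        # weekly anatomy = planning anatomy pulled back through the analytic
        # field, evaluated implicitly for sub-voxel boundary accuracy
        px, py, pz = x + v.vectors[0], y + v.vectors[1], z + v.vectors[2]
        masks_w = _implicit_masks(px, py, pz, grid)
        rsp_w = _implicit_rsp(px, py, pz, masks_w)
        weekly.append((VoxelGrid(rsp_w, grid), StructureSet(masks_w, grid)))
        true_dvfs.append(invert_dvf(v))

    return PatientTimeline(planning, structures, weekly, true_dvfs, params)


def _is_static(params: ProgressionParams) -> bool:
    d = asdict(params)
    d.pop("seed")
    return all(val == 0 for val in d.values())


#: population mean/sd/truncation for cohort sampling, matching the stated
#: course statistics of the emulated cohort.
DEFAULT_POPULATION: dict[str, tuple[float, float, float, float]] = {
    "ctv_high_loss_per_day": (0.015, 0.004, 0.0, 0.03),
    "ctv_node_loss_per_day": (0.023, 0.006, 0.0, 0.032),
    "ctv_elective_loss_per_day": (0.003, 0.0015, 0.0, 0.02),
    "ctv_high_shift_mm": (2.5, 0.4, 1.8, 3.7),
    "ctv_node_shift_mm": (3.2, 0.4, 2.0, 3.7),
    "ctv_elective_shift_mm": (3.4, 0.4, 2.0, 3.7),
    "parotid_total_loss": (0.286, 0.146, 0.0, 0.8),
    "parotid_medial_shift": (2.3, 0.3, 0.0, 5.0),
    "submandibular_total_loss": (0.266, 0.171, 0.0, 0.8),
    "submandibular_medial_shift": (0.3, 0.15, 0.0, 2.0),
    "thyroid_total_loss": (0.123, 0.113, 0.0, 0.6),
    "neck_contraction": (3.0, 1.0, 0.0, 6.0),
    "snrv_sigma": (1.0, 0.0, 0.0, 3.0),
}


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic, platform-stable per-patient seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def draw_params(master_seed: int, index: int,
                population: dict | None = None) -> ProgressionParams:
    population = dict(DEFAULT_POPULATION if population is None else population)
    seed = child_seed(master_seed, index)
    rng = np.random.default_rng(seed)
    values = {}
    for name in sorted(population):
        mean, sd, lo, hi = population[name]
        if sd < 0:
            raise ValueError(f"population sd for {name} must be >= 0 (got {sd})")
        if sd == 0:
            values[name] = float(np.clip(mean, lo, hi))
            continue
        for _ in range(1000):
            val = rng.normal(mean, sd)
            if lo <= val < hi:
                break
        else:
            raise ValueError(f"cannot draw {name} within [{lo}, {hi})")
        values[name] = float(val)
    return ProgressionParams(seed=seed, **values)


def make_cohort(n: int, master_seed: int,
                population: dict | None = None,
                grid: GridSpec = DEFAULT_GRID) -> list[PatientTimeline]:
    """Generate ``n`` patients with parameters drawn from the population."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    return [make_patient(draw_params(master_seed, i, population), grid)
            for i in range(n)]


# --------------------------------------------------------------------------
# persistence (NIfTI + JSON sidecar)
# --------------------------------------------------------------------------

def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _save_nii(arr: np.ndarray, grid: GridSpec, path: Path):
    nib.save(nib.Nifti1Image(arr, _affine(grid)), str(path))


def _load_nii(path: Path) -> tuple[np.ndarray, GridSpec]:
    if not path.exists():
        raise FileNotFoundError(f"missing patient file: {path}")
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    arr = np.asanyarray(img.dataobj)
    grid = GridSpec(tuple(arr.shape[:3]), spacing, origin)
    return arr, grid


def write_patient(timeline: PatientTimeline, directory: str | Path):
    """Persist a timeline: float64 NIfTI grids/DVFs, uint8 masks, JSON params."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    g = timeline.grid
    _save_nii(timeline.planning.values.astype(np.float64), g,
              d / "planning_rsp.nii.gz")
    for name, m in timeline.planning_structures.masks.items():
        _save_nii(m.astype(np.uint8), g, d / f"planning_mask_{name}.nii.gz")
    for w, (vg, ss) in zip(WEEKS, timeline.weekly):
        _save_nii(vg.values.astype(np.float64), g, d / f"week{w}_rsp.nii.gz")
        for name, m in ss.masks.items():
            _save_nii(m.astype(np.uint8), g, d / f"week{w}_mask_{name}.nii.gz")
        dvf = timeline.true_dvfs[w - 1]
        _save_nii(np.moveaxis(dvf.vectors, 0, -1).astype(np.float64), g,
                  d / f"dvf_week{w}.nii.gz")
    (d / "params.json").write_text(json.dumps(asdict(timeline.params),
                                              indent=2, sort_keys=True))


def read_patient(directory: str | Path) -> PatientTimeline:
    d = Path(directory)
    params = ProgressionParams(**json.loads((d / "params.json").read_text()))
    rsp, grid = _load_nii(d / "planning_rsp.nii.gz")
    mask_names = sorted(p.name[len("planning_mask_"):-len(".nii.gz")]
                        for p in d.glob("planning_mask_*.nii.gz"))
    if not mask_names:
        raise FileNotFoundError(f"no planning masks found in {d}")
    planning_masks = {
        name: _load_nii(d / f"planning_mask_{name}.nii.gz")[0].astype(bool)
        for name in mask_names}
    weekly = []
    dvfs = []
    for w in WEEKS:
        rsp_w, _ = _load_nii(d / f"week{w}_rsp.nii.gz")
        masks_w = {
            name: _load_nii(d / f"week{w}_mask_{name}.nii.gz")[0].astype(bool)
            for name in mask_names}
        weekly.append((VoxelGrid(rsp_w, grid), StructureSet(masks_w, grid)))
        vec, _ = _load_nii(d / f"dvf_week{w}.nii.gz")
        dvfs.append(DisplacementField(np.moveaxis(vec, -1, 0), grid))
    return PatientTimeline(VoxelGrid(rsp, grid),
                           StructureSet(planning_masks, grid),
                           weekly, dvfs, params)
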