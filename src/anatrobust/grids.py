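"""Voxel grids, structure sets and displacement fields.

All spatial quantities are in world millimetres.  A grid is an axis-aligned
box: voxel index ``(i, j, k)`` sits at ``origin + index * spacing`` with
axis 0 = x (patient left-right), axis 1 = y (anterior-posterior, +y is
posterior) and axis 2 = z (inferior-superior).  Scalar grids carry relative
stopping power (water = 1) or dose in Gy; displacement fields carry a 3-vector
per voxel in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel lattice: shape, isotropic-or-not spacing, origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the box (mm) along each axis."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_arr)) / 1000.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers as three 1-D arrays."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points to fractional index coordinates."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - self.origin_arr) / self.spacing_arr

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin_arr + idx * self.spacing_arr

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense world-coordinate meshes (each of full grid shape)."""
        cx, cy, cz = self.voxel_centers()
        return np.meshgrid(cx, cy, cz, indexing="ij")


@dataclass
class VoxelGrid:
    """A scalar field (RSP or dose) on a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in grid")

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.grid)

    def sample(self, points_mm: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the field at world points (N, 3)."""
        idx = self.grid.world_to_index(points_mm)
        return ndimage.map_coordinates(
            self.values.astype(float, copy=False), idx.T, order=order,
            mode="constant", cval=cval,
        )


# Dose distributions reuse the scalar-grid container.
DoseGrid = VoxelGrid


@dataclass
class StructureSet:
    """Named binary masks sharing one grid."""

    masks: dict[str, np.ndarray]
    grid: GridSpec
    source_rule: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            self.masks[name] = m.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return sorted(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cc

    def centroid_mm(self, name: str) -> np.ndarray:
        """Mask centroid in world mm (mean of voxel-center coordinates)."""
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValueError(f"mask {name!r} is empty")
        return self.grid.index_to_world(idx.mean(axis=0))[0]

    def copy(self) -> "StructureSet":
        return StructureSet(
            {k: v.copy() for k, v in self.masks.items()}, self.grid,
            dict(self.source_rule),
        )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement (mm), components stacked on axis 0."""

    vectors: np.ndarray  # shape (3,) + grid.shape
    grid: GridSpec

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (3,) + self.grid.shape:
            raise ValueError("displacement field shape mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite displacement values")

    @classmethod
    def zeros(cls, grid: GridSpec) -> "DisplacementField":
        return cls(np.zeros((3,) + grid.shape), grid)

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.vectors) <= atol))

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors ** 2).sum(axis=0))

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear displacement vectors at world points (N, 3)."""
        idx = self.grid.world_to_index(points_mm).T
        return np.stack(
            [ndimage.map_coordinates(self.vectors[c], idx, order=1,
                                     mode="nearest") for c in range(3)],
            axis=1,
        )


def warp_scalar(values: np.ndarray, dvf: DisplacementField, order: int = 1,
                cval: float = 0.0) -> np.ndarray:
    """Pull-back warp: ``out(x) = values(x + u(x))`` on the field's grid.

    ``order=0`` gives nearest-neighbour sampling (binary masks stay binary).
    """
    g = dvf.grid
    disp_idx = dvf.vectors / g.spacing_arr[:, None, None, None]
    base = np.indices(g.shape, dtype=float)
    coords = base + disp_idx
    return ndimage.map_coordinates(
        np.asarray(values, dtype=float), coords, order=order,
        mode="constant", cval=cval,
    )


def warp_mask(mask: np.ndarray, dvf: DisplacementField) -> np.ndarray:
    """Nearest-neighbour warp of a binary mask (contour propagation)."""
    return warp_scalar(mask.astype(np.float32), dvf, order=0) > 0.5


def _damped_inverse_iteration(dvf: DisplacementField, v0: np.ndarray,
                              n_iter: int, tol_mm: float, alpha: float
                              ) -> np.ndarray:
    g = dvf.grid
    base = np.indices(g.shape, dtype=float) * g.spacing_arr[:, None, None, None]
    base += g.origin_arr[:, None, None, None]
    v = v0
    for _ in range(n_iter):
        pts = (base + v).reshape(3, -1).T
        u_at = dvf.sample(pts).T.reshape(v.shape)
        v_new = (1.0 - alpha) * v + alpha * (-u_at)
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol_mm:
            break
    return v


def invert_dvf(dvf: DisplacementField, n_iter: int = 60, tol_mm: float = 0.02,
               alpha: float = 0.65, coarse: bool = True) -> DisplacementField:
    """Numerically invert a displacement field.

    Solves ``v(y) = -u(y + v(y))`` (the inverse of ``phi(x) = x + u(x)``) by
    damped fixed-point iteration, which converges for any diffeomorphism whose
    local expansion stays below ``2/alpha - 1``.  For speed the bulk of the
    iterations run on a half-resolution copy of the smooth field; a few
    full-resolution sweeps polish the result.
    """
    g = dvf.grid
    if coarse and min(g.shape) >= 16:
        cg = GridSpec(tuple(max(s // 2, 8) for s in g.shape),
                      tuple(sp * (s - 1) / (max(s // 2, 8) - 1)
                            for s, sp in zip(g.shape, g.spacing)),
                      g.origin)
        zoom = [cs / s for cs, s in zip(cg.shape, g.shape)]
        cvec = np.stack([ndimage.zoom(dvf.vectors[c], zoom, order=1)
                         for c in range(3)])
        cdvf = DisplacementField(cvec, cg)
        v_c = _damped_inverse_iteration(cdvf, np.zeros_like(cvec),
                                        n_iter, tol_mm, alpha)
        back = [s / cs for cs, s in zip(cg.shape, g.shape)]
        v0 = np.stack([ndimage.zoom(v_c[c], back, order=1)[
            tuple(slice(0, s) for s in g.shape)] for c in range(3)])
        if v0.shape != (3,) + g.shape:  # zoom rounding
            pad = [(0, t - s) for t, s in zip((3,) + g.shape, v0.shape)]
            v0 = np.pad(v0, pad, mode="edge")
        v = _damped_inverse_iteration(dvf, v0, 10, tol_mm, alpha)
    else:
        v = _damped_inverse_iteration(dvf, np.zeros_like(dvf.vectors),
                                      n_iter, tol_mm, alpha)
    return DisplacementField(v, g)


def inversion_residual_voxels(dvf: DisplacementField, inv: DisplacementField
                              ) -> np.ndarray:
    """Per-voxel |phi(psi(y)) - y| in voxel units (composition residual)."""
    g = dvf.grid
    base = np.indices(g.shape, dtype=float) * g.spacing_arr[:, None, None, None]
    base += g.origin_arr[:, None, None, None]
    pts = (base + inv.vectors).reshape(3, -1).T
    u_at = dvf.sample(pts).T.reshape(inv.vectors.shape)
    resid_mm = inv.vectors + u_at
    return (np.abs(resid_mm) / g.spacing_arr[:, None, None, None]).max(axis=0)
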