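"""Regular-grid geometry and displacement-field algebra.

Conventions used throughout the package:

* 0-based voxel indices; the world position of voxel index ``i`` is
  ``origin + i * spacing`` (voxel-*center* convention), world axes aligned
  with grid axes, all lengths in mm.
* A :class:`VectorField` lives on the *target* (start-of-treatment, SOT)
  grid and maps target world points into source (end-of-treatment, EOT)
  space via ``phi(x) = x + u(x)``.  A zero field is the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "VectorField",
    "ROIMask",
    "ROI_NAMES",
    "FieldInversionError",
    "trilinear_sample",
    "warp_volume",
    "compose_fields",
    "invert_field",
    "jacobian_determinant",
]

#: Canonical ROI names scored by the benchmark.
ROI_NAMES = ("brainstem", "cord", "mandible", "parotid_l", "parotid_r", "external")


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned regular voxel grid in physical (mm) coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("ImageGrid is strictly 3-D")
        if any(n < 2 for n in shape):
            raise ValueError(f"every axis needs >= 2 voxels, got shape {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacings must be strictly positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate transforms -------------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``shape + (3,)``."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size from first to last voxel center, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class ScalarVolume:
    """One real value per voxel (HU for images, Gy for dose, mm for TRE maps)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")


@dataclass
class VectorField:
    """Displacement field u(x) in mm on a regular grid; phi(x) = x + u(x)."""

    grid: ImageGrid
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != self.grid.shape + (3,):
            raise ValueError(
                f"displacements shape {self.displacements.shape} != "
                f"{self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("vector field contains non-finite displacements")

    @classmethod
    def zero(cls, grid: ImageGrid) -> "VectorField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def magnitude(self) -> ScalarVolume:
        return ScalarVolume(self.grid, np.linalg.norm(self.displacements, axis=-1))


@dataclass
class ROIMask:
    """Boolean organ membership on a grid."""

    grid: ImageGrid
    name: str
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.membership.any():
            raise ValueError(f"ROI mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


class FieldInversionError(RuntimeError):
    """Raised when fixed-point field inversion fails to converge.

    Carries the residual displacement-update map (mm) for diagnosis.
    """

    def __init__(self, message: str, residual: np.ndarray):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# sampling


def _as_points(points: Sequence) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 components")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates")
    return pts


def trilinear_sample(
    volume: ScalarVolume,
    points: Sequence,
    fill: float | None = None,
    return_outside: bool = False,
):
    """Trilinear interpolation of ``volume`` at world-mm ``points``.

    Points outside the hull of voxel centers receive ``fill`` (default: the
    volume minimum, appropriate for CT-like data; pass 0.0 for dose) and are
    flagged in the optional outside mask.
    """
    pts = _as_points(points)
    shape_in = pts.shape[:-1]
    pts = pts.reshape(-1, 3)
    idx = volume.grid.world_to_index(pts)
    n = np.asarray(volume.grid.shape)
    outside = np.any((idx < 0) | (idx > n - 1), axis=1)
    vals = map_coordinates(volume.values, idx.T, order=1, mode="nearest")
    if fill is None:
        fill = float(volume.values.min())
    vals[outside] = fill
    vals = vals.reshape(shape_in)
    outside = outside.reshape(shape_in)
    if return_outside:
        return vals, outside
    return vals


def _sample_field(field: VectorField, points: np.ndarray) -> np.ndarray:
    """Sample a displacement field at world points (edge-clamped, per component)."""
    pts = _as_points(points).reshape(-1, 3)
    idx = field.grid.world_to_index(pts).T
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        out[:, c] = map_coordinates(
            field.displacements[..., c], idx, order=1, mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# field algebra


def warp_volume(
    moving: ScalarVolume, field: VectorField, fill: float | None = None
) -> ScalarVolume:
    """Pull-back warp: ``out(x) = moving(x + u(x))`` on the field's (target) grid."""
    x = field.grid.world_coordinates().reshape(-1, 3)
    pts = x + field.displacements.reshape(-1, 3)
    vals = trilinear_sample(moving, pts, fill=fill)
    return ScalarVolume(field.grid, vals.reshape(field.grid.shape))


def compose_fields(outer: VectorField, inner: VectorField) -> VectorField:
    """Composition ``phi_outer o phi_inner`` as a single displacement field.

    ``w(x) = u_inner(x) + u_outer(x + u_inner(x))`` so that
    ``x + w(x) = phi_outer(phi_inner(x))``.
    """
    if outer.grid != inner.grid:
        raise ValueError("compose_fields requires both fields on the same grid")
    x = inner.grid.world_coordinates().reshape(-1, 3)
    u_in = inner.displacements.reshape(-1, 3)
    w = u_in + _sample_field(outer, x + u_in)
    return VectorField(inner.grid, w.reshape(inner.grid.shape + (3,)))


def invert_field(
    field: VectorField, tol: float = 0.01, max_iter: int = 50
) -> VectorField:
    """Invert a small-deformation diffeomorphism by fixed-point iteration.

    Iterates ``v_{k+1}(y) = -u(y + v_k(y))`` until the max update falls
    below ``tol`` (mm).  Requires a strictly positive Jacobian determinant.
    """
    jac = jacobian_determinant(field)
    if jac.values.min() <= 0:
        raise ValueError(
            f"field is not invertible: min Jacobian determinant "
            f"{jac.values.min():.4f} <= 0"
        )
    y = field.grid.world_coordinates().reshape(-1, 3)
    v = np.zeros_like(y)
    for _ in range(max_iter):
        v_new = -_sample_field(field, y + v)
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol:
            return VectorField(field.grid, v.reshape(field.grid.shape + (3,)))
    residual = (v + _sample_field(field, y + v)).reshape(field.grid.shape + (3,))
    raise FieldInversionError(
        f"inversion did not converge in {max_iter} iterations "
        f"(last update {delta:.4g} mm > tol {tol} mm)",
        residual=residual,
    )


def jacobian_determinant(field: VectorField) -> ScalarVolume:
    """``det(I + grad u)`` by central differences in physical (mm) coordinates."""
    if any(n < 3 for n in field.grid.shape):
        raise ValueError("jacobian needs >= 3 voxels per axis")
    sp = field.grid.spacing
    J = np.empty(field.grid.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.displacements[..., i], *sp, axis=(0, 1, 2))
        for j in range(3):
            J[..., i, j] = grads[j]
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return ScalarVolume(field.grid, np.linalg.det(J))
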