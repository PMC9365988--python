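"""Spatial transforms: exact affine inversion, numerical deformation-field
inversion by damped fixed-point iteration, composition and point mapping.

Semantics
---------
A transform here is always a *point map* on world-mm coordinates.  The
normalization transform estimated by the registration module maps
standard-space points to the matching individual-space location (that is the
map used to resample an individual image onto the standard grid).  Its
inverse maps individual-space points into standard space and is what pulls
atlas regions onto the individual grid.

A :class:`DeformationField` stores per-voxel displacement vectors (mm) on a
reference grid with its own affine; applying it to a world point adds the
trilinearly interpolated displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConvergenceError, FormatError, GeometryError

__all__ = [
    "AffineTransform",
    "DeformationField",
    "InverseDeformation",
    "invert_affine",
    "invert_deformation",
    "compose",
    "apply_to_points",
    "jacobian_determinant",
    "read_affine",
    "write_affine",
    "read_deformation",
    "write_deformation",
]


@dataclass
class AffineTransform:
    """A 4x4 world->world affine map (12 free parameters)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (3, N) world points."""
        points = np.asarray(points, dtype=float)
        return self.matrix[:3, :3] @ points + self.matrix[:3, 3:4]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on a reference grid.

    ``displacement`` has shape (X, Y, Z, 3); ``affine`` maps reference-grid
    voxel indices to world mm.  The field's point map is
    ``x -> x + d(x)`` with d interpolated trilinearly (zero-gradient beyond
    the grid edge).
    """

    displacement: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite everywhere")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("reference grid affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def sample_displacement(self, points: np.ndarray) -> np.ndarray:
        """Trilinear displacement (3, N) at world points (3, N)."""
        inv = np.linalg.inv(self.affine)
        vox = inv[:3, :3] @ np.asarray(points, dtype=float) + inv[:3, 3:4]
        out = np.empty_like(vox)
        for c in range(3):
            out[c] = ndimage.map_coordinates(
                self.displacement[..., c], vox, order=1, mode="nearest"
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points + self.sample_displacement(points)

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        """Boolean (N,) flag: point falls inside the reference grid."""
        inv = np.linalg.inv(self.affine)
        vox = inv[:3, :3] @ np.asarray(points, dtype=float) + inv[:3, 3:4]
        shp = np.array(self.shape, dtype=float)[:, None]
        return ((vox >= 0) & (vox <= shp - 1)).all(axis=0)

    def magnitude_voxels(self) -> np.ndarray:
        """Per-voxel displacement magnitude in units of the grid voxel size."""
        return np.linalg.norm(self.displacement / self.voxel_size, axis=-1)


Transform = Union[AffineTransform, DeformationField]


@dataclass
class InverseDeformation(DeformationField):
    """A numerically inverted deformation field with its achieved residual.

    ``residual`` is the maximum interior magnitude, in voxels, of
    ``forward(inverse(x)) - x``; ``provenance`` points at the forward field.
    """

    residual: float = 0.0
    provenance: DeformationField | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def invert_affine(t: AffineTransform) -> AffineTransform:
    """Exact matrix inverse of an affine transform."""
    det = np.linalg.det(t.matrix)
    if abs(det) < 1e-12:
        raise ValueError("cannot invert a singular affine transform")
    return AffineTransform(np.linalg.inv(t.matrix))


def _interior_mask(shape: tuple[int, int, int], margin: int = 1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, s - margin) for s in shape)
    if all(s.stop > s.start for s in sl):
        m[sl] = True
    return m


def invert_deformation(
    d: DeformationField,
    tol: float = 0.01,
    max_iter: int = 100,
    target_shape: tuple[int, int, int] | None = None,
    target_affine: np.ndarray | None = None,
) -> InverseDeformation:
    """Invert a deformation field by damped fixed-point iteration.

    Solves ``e(x) = -d(x + e(x))`` so that ``(x + e(x)) + d(x + e(x)) = x``,
    i.e. forward-then-inverse composes to the identity.  ``tol`` is the
    stopping threshold on the per-iteration update, in voxels of the target
    grid; the step is halved whenever the update grows (oscillation damping).
    The inverse is evaluated on ``target`` (default: the forward field's own
    grid); in the parcellation pipeline the target is the individual image
    grid, where the atlas masks are resampled.

    Raises :class:`ConvergenceError` when the achieved interior composition
    residual exceeds ``10 * tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if target_shape is None:
        target_shape = d.shape
    if target_affine is None:
        target_affine = d.affine.copy()
    target_affine = np.asarray(target_affine, dtype=float)
    vox_size = np.linalg.norm(target_affine[:3, :3], axis=0)
    min_vox = float(vox_size.min())

    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    x = target_affine[:3, :3] @ idx + target_affine[:3, 3:4]

    e = np.zeros_like(x)
    step = 1.0
    prev_update = np.inf
    for _ in range(max_iter):
        e_new = -d.sample_displacement(x + e)
        delta = e_new - e
        update = float(np.abs(delta).max() / min_vox)
        if update > prev_update:  # oscillation: under-relax
            step = max(step * 0.5, 0.125)
        e = e + step * delta
        prev_update = update
        if update * step < tol:
            break

    resid_vec = (e + d.sample_displacement(x + e)) / min_vox
    resid = np.linalg.norm(resid_vec, axis=0).reshape(target_shape)
    interior = _interior_mask(target_shape)
    max_resid = float(resid[interior].max()) if interior.any() else float(resid.max())
    if max_resid > 10 * tol:
        worst = np.unravel_index(np.argmax(np.where(interior, resid, -1)), target_shape)
        raise ConvergenceError(
            f"field inversion residual {max_resid:.4f} voxels > {10 * tol:.4f} "
            f"(worst voxel {worst})"
        )
    disp = e.T.reshape(*target_shape, 3)
    return InverseDeformation(disp, target_affine, residual=max_resid, provenance=d)


# ---------------------------------------------------------------------------
# Composition and application
# ---------------------------------------------------------------------------

def compose(
    outer: Transform,
    inner: Transform,
    grid_shape: tuple[int, int, int] | None = None,
    grid_affine: np.ndarray | None = None,
) -> Transform:
    """Compose two transforms: the result maps ``x -> outer(inner(x))``.

    Two affines compose exactly to an affine (matrix product).  Any
    combination involving a deformation field is sampled onto a reference
    grid (default: the inner field's grid, else the outer's) and returned as
    a :class:`DeformationField`.
    """
    if isinstance(outer, AffineTransform) and isinstance(inner, AffineTransform):
        return AffineTransform(outer.matrix @ inner.matrix)

    if grid_affine is None or grid_shape is None:
        ref = inner if isinstance(inner, DeformationField) else outer
        if not isinstance(ref, DeformationField):  # pragma: no cover
            raise GeometryError("no reference grid available for composition")
        grid_shape, grid_affine = ref.shape, ref.affine.copy()
    grid_affine = np.asarray(grid_affine, dtype=float)

    idx = np.indices(grid_shape, dtype=float).reshape(3, -1)
    x = grid_affine[:3, :3] @ idx + grid_affine[:3, 3:4]
    y = inner.apply(x)
    z = outer.apply(y)
    disp = (z - x).T.reshape(*grid_shape, 3)
    return DeformationField(disp, grid_affine)


def apply_to_points(
    t: Transform, points: np.ndarray, return_mask: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Map (3, N) world points through a transform.

    For deformation fields the displacement is interpolated trilinearly; with
    ``return_mask=True`` a boolean per-point flag marks points inside the
    field's domain (outside points use edge displacements).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    mapped = t.apply(points)
    if return_mask:
        mask = (
            t.in_domain(points)
            if isinstance(t, DeformationField)
            else np.ones(points.shape[1], dtype=bool)
        )
        return mapped, mask
    return mapped


def jacobian_determinant(d: DeformationField) -> np.ndarray:
    """Voxel-wise Jacobian determinant of the map ``x -> x + d(x)``.

    Central finite differences in world coordinates; positive everywhere for
    a locally invertible (orientation-preserving) field.
    """
    A = d.affine[:3, :3]
    inv_A = np.linalg.inv(A)
    J = np.empty(d.shape + (3, 3))
    for c in range(3):
        grads = np.gradient(d.displacement[..., c])  # d component c / d voxel axis
        dvox = np.stack(grads, axis=-1)  # (X,Y,Z,3)
        # convert derivative wrt voxel index to derivative wrt world mm
        J[..., c, :] = dvox @ inv_A
    J += np.eye(3)
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Storage: 4x4 plain-text matrix; 5D displacement NIfTI (x,y,z,1,3) in mm
# ---------------------------------------------------------------------------

def write_affine(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.12g")


def read_affine(path: str | Path) -> AffineTransform:
    m = np.loadtxt(str(path))
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return AffineTransform(m)


def write_deformation(d: DeformationField, path: str | Path) -> None:
    arr = d.displacement[:, :, :, None, :]  # (X,Y,Z,1,3)
    img = nib.Nifti1Image(arr, d.affine)
    img.header.set_qform(d.affine, code=1)
    img.header.set_sform(d.affine, code=1)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_deformation(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 5 and arr.shape[3] == 1 and arr.shape[4] == 3:
        arr = arr[:, :, :, 0, :]
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise FormatError(f"{path}: expected 5D (x,y,z,1,3) displacement NIfTI")
    return DeformationField(arr, img.affine)
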