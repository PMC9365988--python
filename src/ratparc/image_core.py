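"""Volumetric data model, NIfTI I/O, geometric bookkeeping and B-spline resampling.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based; the continuous voxel coordinate ``i.0`` is the
  voxel centre.
* World coordinates (mm) follow the NIfTI affine (RAS+): ``world = A @ [i,j,k,1]``.
* Interpolation is polynomial B-spline of degree 0/1/3/4; for degree >= 2 the
  samples are converted to spline coefficients first (true interpolation, not
  smoothing).  "4th-degree B-spline" is the default used when warping masks
  and normalizing images, matching the convention of SPM-style pipelines.
* Sampling outside the input domain yields 0 (constant padding): brain images
  and masks are 0 outside the head, so this does not inflate structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, FormatError

__all__ = [
    "Volume3D",
    "Series4D",
    "LabelAtlas",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_lut",
    "write_lut",
    "scale_voxels",
    "set_origin",
    "resample",
    "SUPPORTED_DEGREES",
]

SUPPORTED_DEGREES = (0, 1, 3, 4)


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel-index -> world-mm affine.

    Houses every single-volume image role in the pipeline: individual
    MEMRI/T2WI images, the standard-space template, tissue probability maps,
    label images and masks.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"Volume3D requires a 3D array, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the spatial affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        """Map (3, N) continuous voxel coordinates to world mm."""
        vox = np.asarray(vox, dtype=float)
        return self.affine[:3, :3] @ vox + self.affine[:3, 3:4]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return inv[:3, :3] @ world + inv[:3, 3:4]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (3, nvox)."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1)
        return self.voxel_to_world(idx)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.affine.copy())

    def same_grid(self, other: "Volume3D", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class Series4D:
    """An ordered 4D series of volumes sharing one grid (a MEMRI repetition run)."""

    volumes: list[Volume3D]
    times: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) < 1:
            raise ValueError("Series4D requires at least one volume")
        first = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.same_grid(first):
                raise ValueError("all volumes in a series must share shape and affine")
        if not self.times:
            self.times = list(range(len(self.volumes)))
        if len(self.times) != len(self.volumes):
            raise ValueError("times must match the number of volumes")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def affine(self) -> np.ndarray:
        return self.volumes[0].affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def to_array(self) -> np.ndarray:
        return np.stack([v.data for v in self.volumes], axis=-1)


@dataclass
class LabelAtlas:
    """Integer-labelled volume plus an index -> region-name lookup table.

    Index 0 is reserved for background; every nonzero voxel value must be
    present in the lookup table and indices are unique.
    """

    labels: Volume3D
    lut: dict[int, str]

    def __post_init__(self) -> None:
        data = self.labels.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.with_data(np.round(data).astype(np.int32))
        if self.labels.data.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        if 0 in self.lut:
            raise ValueError("index 0 is reserved for background")
        present = set(np.unique(self.labels.data)) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"labels missing from lookup table: {sorted(missing)}")

    @property
    def indices(self) -> list[int]:
        """Sorted nonzero label values actually present in the image."""
        vals = np.unique(self.labels.data)
        return [int(v) for v in vals if v != 0]


@dataclass
class BinaryMask:
    """A single-ROI {0,1} image with its originating atlas index."""

    data: Volume3D
    source_index: int = 0

    def __post_init__(self) -> None:
        arr = self.data.data
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if arr.dtype != np.uint8:
            self.data = self.data.with_data(arr.astype(np.uint8))

    @property
    def array(self) -> np.ndarray:
        return self.data.data

    @property
    def voxel_count(self) -> int:
        return int(self.array.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI-1 volume (.nii or .nii.gz)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} is {data.ndim}D; read_volume expects a 3D image"
        )
    return Volume3D(data, img.affine)


def write_volume(v: Volume3D, path: str | Path) -> None:
    img = nib.Nifti1Image(v.data, v.affine)
    img.header.set_qform(v.affine, code=1)
    img.header.set_sform(v.affine, code=1)
    nib.save(img, str(path))


def read_series(path: str | Path) -> Series4D:
    """Read a 4D NIfTI file as an ordered series."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path} is {data.ndim}D; expected a 4D series")
    vols = [Volume3D(data[..., t], img.affine) for t in range(data.shape[3])]
    return Series4D(vols)


def write_series(s: Series4D, path: str | Path) -> None:
    img = nib.Nifti1Image(s.to_array(), s.affine)
    img.header.set_qform(s.affine, code=1)
    img.header.set_sform(s.affine, code=1)
    nib.save(img, str(path))


def read_lut(path: str | Path) -> dict[int, str]:
    """Read a tab-separated ``index<TAB>name`` lookup table."""
    lut: dict[int, str] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["index", "name"]:
        raise FormatError(f"{path}: expected header 'index<TAB>name'")
    for line in lines[1:]:
        if not line.strip():
            continue
        idx_s, name = line.split("\t", 1)
        idx = int(idx_s)
        if idx in lut:
            raise FormatError(f"{path}: duplicate index {idx}")
        lut[idx] = name.strip()
    return lut


def write_lut(lut: dict[int, str], path: str | Path) -> None:
    lines = ["index\tname"] + [f"{i}\t{n}" for i, n in sorted(lut.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometric bookkeeping
# ---------------------------------------------------------------------------

def scale_voxels(v: Volume3D, factor: float) -> Volume3D:
    """Uniformly zoom the world geometry by ``factor`` (data untouched).

    Rodent images have mm-scale heads; registration machinery tuned for human
    heads expects cm-scale objects, so voxel sizes are conventionally enlarged
    (e.g. tenfold) before spatial normalization.  The whole spatial part of
    the affine, including the translation, is scaled so that the zoom is a
    pure similarity of world space.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    affine = v.affine.copy()
    affine[:3, :4] *= factor
    return Volume3D(v.data, affine)


def set_origin(v: Volume3D, point: Sequence[float], world: bool = False) -> Volume3D:
    """Move the world origin (0,0,0) to the designated voxel.

    ``point`` is a continuous voxel coordinate by default (the landmark voxel,
    e.g. the dorsal third ventricle in rat studies); pass ``world=True`` to
    give the landmark's current world-mm position instead.  Data untouched.
    With voxel semantics the operation is idempotent.
    """
    point = np.asarray(point, dtype=float)
    if not np.isfinite(point).all() or point.shape != (3,):
        raise ValueError("origin point must be a finite triple")
    vox = v.world_to_voxel(point[:, None])[:, 0] if world else point
    affine = v.affine.copy()
    affine[:3, 3] = -affine[:3, :3] @ vox
    return Volume3D(v.data, affine)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def snap_to_edges(coords: np.ndarray, shape: Sequence[int], eps: float = 1e-6) -> np.ndarray:
    """Snap coordinates within ``eps`` voxels of the grid boundary onto it.

    Constant-padding interpolation treats any coordinate beyond [0, n-1] as
    outside; floating-point round-trip error of order 1e-15 voxels would
    otherwise randomly zero out edge voxels under identity mappings.
    """
    for a, n in enumerate(shape):
        c = coords[a]
        np.copyto(c, 0.0, where=np.abs(c) < eps)
        np.copyto(c, float(n - 1), where=np.abs(c - (n - 1)) < eps)
    return coords


def resample(
    v: Volume3D,
    mapping: Callable[[np.ndarray], np.ndarray] | None = None,
    degree: int = 4,
    out_shape: tuple[int, int, int] | None = None,
    out_affine: np.ndarray | None = None,
) -> Volume3D:
    """Resample ``v`` onto an output grid through a voxel-coordinate mapping.

    Parameters
    ----------
    mapping
        Callable taking (3, N) *output* voxel coordinates and returning the
        corresponding (3, N) continuous *input* voxel coordinates.  ``None``
        means the world-identity map between the two grids (pure regridding).
    degree
        B-spline degree, one of {0, 1, 3, 4}.  Degrees >= 2 are prefiltered
        so that the result interpolates the samples exactly.
    out_shape, out_affine
        Output grid; default is the input grid.
    """
    if degree not in SUPPORTED_DEGREES:
        raise ValueError(f"degree must be one of {SUPPORTED_DEGREES}, got {degree}")
    if out_shape is None:
        out_shape = v.shape
    if out_affine is None:
        out_affine = v.affine.copy()
    out_affine = np.asarray(out_affine, dtype=float)
    if abs(np.linalg.det(out_affine[:3, :3])) < 1e-12:
        raise ValueError("output affine is not invertible")

    out_vox = np.indices(out_shape, dtype=float).reshape(3, -1)
    if mapping is None:
        m = np.linalg.inv(v.affine) @ out_affine
        in_vox = m[:3, :3] @ out_vox + m[:3, 3:4]
    else:
        in_vox = np.asarray(mapping(out_vox), dtype=float)
        if not np.isfinite(in_vox).all():
            raise ValueError("mapping produced non-finite coordinates")
    in_vox = snap_to_edges(in_vox, v.shape)

    vals = ndimage.map_coordinates(
        v.data.astype(float), in_vox, order=degree, mode="constant", cval=0.0,
        prefilter=True,
    )
    return Volume3D(vals.reshape(out_shape), out_affine)


def world_map_to_voxel_mapping(
    out_affine: np.ndarray,
    in_affine: np.ndarray,
    world_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build a resample() mapping: output voxel -> world -> (world_fn) -> input voxel."""
    inv_in = np.linalg.inv(in_affine)

    def mapping(out_vox: np.ndarray) -> np.ndarray:
        world = out_affine[:3, :3] @ out_vox + out_affine[:3, 3:4]
        if world_fn is not None:
            world = world_fn(world)
        return inv_in[:3, :3] @ world + inv_in[:3, 3:4]

    return mapping
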