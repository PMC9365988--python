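"""Registration: individual -> standard-space transform estimation.

Two paths mirror the two ways an individual rodent image can be normalized:

* **template path** — intensity-based affine (12-parameter) registration to a
  template image, optionally followed by a nonlinear refinement, yielding a
  total displacement field on the template grid;
* **TPM path** — diffeomorphic registration of tissue probability maps via a
  stationary velocity field exponentiated by scaling-and-squaring (the
  "exponentiated Lie" family), guaranteeing a positive Jacobian.

All estimated transforms are *point maps from standard space to individual
space* (the map that resamples the individual image onto the standard grid);
their inverses, computed in :mod:`ratparc.transforms`, pull atlas regions
onto the individual grid.

Everything is deterministic: derivative-free Powell optimization over a
fixed Gaussian pyramid, no random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import RegistrationError
from .image_core import (Volume3D, Series4D, resample, snap_to_edges,
                         world_map_to_voxel_mapping)
from .transforms import AffineTransform, DeformationField, Transform

__all__ = [
    "RigidParams",
    "register_affine",
    "register_rigid",
    "register_nonlinear",
    "register_diffeomorphic",
    "exponentiate_velocity",
    "integrate_velocity_euler",
    "realign_series",
    "normalize_image",
]


@dataclass
class RigidParams:
    """Six rigid-body parameters: translations (mm) and rotations (radians)."""

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        if not (np.isfinite(self.translation).all() and np.isfinite(self.rotation).all()):
            raise ValueError("rigid parameters must be finite")

    @classmethod
    def identity(cls) -> "RigidParams":
        return cls(np.zeros(3), np.zeros(3))


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4 world matrix, rotating/scaling about ``center``.

    Layout: 3 translations (mm), 3 rotations (rad), 3 log-free scales
    (1 + s), 3 shears.
    """
    t = p[0:3]
    R = _rotation_matrix(*p[3:6])
    S = np.diag(1.0 + p[6:9])
    H = np.eye(3)
    H[0, 1], H[0, 2], H[1, 2] = p[9], p[10], p[11]
    A3 = R @ S @ H
    M = np.eye(4)
    M[:3, :3] = A3
    M[:3, 3] = t + center - A3 @ center
    return M


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------

def _level_factors(shape: Sequence[int], f: int, min_len: int = 12) -> tuple[int, ...]:
    out = []
    for s in shape:
        fa = f
        while fa > 1 and s // fa < min_len:
            fa //= 2
        out.append(max(fa, 1))
    return tuple(out)


def _decimate(v: Volume3D, fac: tuple[int, ...]) -> Volume3D:
    if all(f == 1 for f in fac):
        return v
    sig = [0.5 * f if f > 1 else 0.0 for f in fac]
    data = ndimage.gaussian_filter(v.data.astype(float), sig, mode="nearest")
    data = data[:: fac[0], :: fac[1], :: fac[2]]
    affine = v.affine.copy()
    affine[:3, :3] = affine[:3, :3] * np.array(fac)
    return Volume3D(data, affine)


# ---------------------------------------------------------------------------
# Similarity metrics (negated: lower is better)
# ---------------------------------------------------------------------------

def _neg_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return -float((a * b).sum() / denom)


def _neg_mi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = (p[nz] * np.log(p[nz] / (px @ py)[nz])).sum()
    return -float(mi)


_METRICS = {"ncc": _neg_ncc, "mi": _neg_mi}


# ---------------------------------------------------------------------------
# Affine / rigid registration
# ---------------------------------------------------------------------------

def _check_nondegenerate(moving: Volume3D, fixed: Volume3D) -> None:
    if float(np.std(moving.data)) == 0.0 or float(np.std(fixed.data)) == 0.0:
        raise RegistrationError("cannot register a constant (degenerate) image")


def _sample_moving(moving: Volume3D, world_pts: np.ndarray) -> np.ndarray:
    vox = snap_to_edges(moving.world_to_voxel(world_pts), moving.shape)
    return ndimage.map_coordinates(
        moving.data.astype(float), vox, order=1, mode="constant", cval=0.0
    )


def _optimize_levels(
    moving: Volume3D,
    fixed: Volume3D,
    metric: str,
    stages: list[tuple[int, list[int]]],
    p0: np.ndarray,
) -> np.ndarray:
    """Run Powell over a coarse-to-fine schedule.

    ``stages`` is a list of (pyramid factor, free-parameter index list); the
    12-vector ``p0`` is refined in place order.
    """
    metric_fn = _METRICS[metric]
    center = fixed.voxel_to_world(
        (np.array(fixed.shape, dtype=float)[:, None] - 1) / 2.0
    )[:, 0]
    p = p0.copy()
    for f, free in stages:
        fac = _level_factors(fixed.shape, f)
        fixed_l = _decimate(fixed, fac)
        moving_l = _decimate(moving, _level_factors(moving.shape, f))
        X = fixed_l.world_grid()
        fvals = fixed_l.data.ravel().astype(float)
        scales = np.concatenate(
            [np.maximum(fixed_l.voxel_size, 1e-6), [0.05] * 9]
        )

        def cost(u: np.ndarray, free=free, X=X, fvals=fvals,
                 moving_l=moving_l, scales=scales) -> float:
            q = p.copy()
            q[free] = u * scales[free]
            M = params_to_matrix(q, center)
            warped = _sample_moving(moving_l, M[:3, :3] @ X + M[:3, 3:4])
            return metric_fn(fvals, warped)

        u0 = p[free] / scales[free]
        res = optimize.minimize(
            cost,
            u0,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 80},
        )
        p[free] = res.x * scales[free]
    return p


def register_affine(
    moving: Volume3D,
    fixed: Volume3D,
    metric: str = "ncc",
    dof: int = 12,
) -> AffineTransform:
    """Estimate the 12-parameter transform aligning ``moving`` to ``fixed``.

    Returns the point map *fixed world -> moving world* (standard ->
    individual), i.e. the transform that resamples the individual onto the
    standard grid.  ``metric`` is ``"ncc"`` (normalized cross-correlation,
    same modality) or ``"mi"`` (32-bin mutual information, cross-modality).
    Deterministic given identical inputs and settings.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9 or 12")
    _check_nondegenerate(moving, fixed)

    trans, rigid = list(range(3)), list(range(6))
    sim, full = list(range(9)), list(range(12))
    stages: list[tuple[int, list[int]]] = [(4, trans), (4, rigid), (2, rigid)]
    if dof >= 9:
        stages.append((2, sim))
    stages.append((1, rigid if dof == 6 else (sim if dof == 9 else full)))

    p = _optimize_levels(moving, fixed, metric, stages, np.zeros(12))
    center = fixed.voxel_to_world(
        (np.array(fixed.shape, dtype=float)[:, None] - 1) / 2.0
    )[:, 0]
    return AffineTransform(params_to_matrix(p, center))


def register_rigid(
    moving: Volume3D, fixed: Volume3D, metric: str = "ncc"
) -> tuple[AffineTransform, RigidParams]:
    """Six-parameter rigid registration (used for series realignment)."""
    _check_nondegenerate(moving, fixed)
    stages = [(2, list(range(3))), (2, list(range(6))), (1, list(range(6)))]
    p = _optimize_levels(moving, fixed, metric, stages, np.zeros(12))
    center = fixed.voxel_to_world(
        (np.array(fixed.shape, dtype=float)[:, None] - 1) / 2.0
    )[:, 0]
    return (
        AffineTransform(params_to_matrix(p, center)),
        RigidParams(p[0:3], p[3:6]),
    )


# ---------------------------------------------------------------------------
# Nonlinear (template path)
# ---------------------------------------------------------------------------

def _world_gradient(arr: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Gradient of a grid image with respect to world mm, shape (3, nvox)."""
    gv = np.stack([g.ravel() for g in np.gradient(arr)])  # d/d voxel index
    inv_A3 = np.linalg.inv(affine[:3, :3])
    return inv_A3.T @ gv


def _demons_force(
    fixed_vals: np.ndarray,
    warped: np.ndarray,
    grad_world: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Classic demons update (mm), per point: -diff * g / (|g|^2 + diff^2)."""
    diff = (warped - fixed_vals) / scale
    g = grad_world / scale
    denom = (g * g).sum(axis=0) + diff * diff + 1e-12
    return -diff * g / denom


def register_nonlinear(
    moving: Volume3D,
    fixed: Volume3D,
    init: AffineTransform | None = None,
    grid_spacing: np.ndarray | float | None = None,
    reg_weight: float = 1.0,
    iterations: tuple[int, ...] = (40, 20),
) -> DeformationField:
    """Nonlinear refinement on top of an affine initialization.

    An iterative intensity-driven scheme: at each step the residual between
    the fixed image and the warped moving image drives a demons-type force
    along the image gradient.  Regularization is fluid-like: each *update*
    is smoothed with a Gaussian kernel of ``grid_spacing * reg_weight``
    (default: 2 fixed-grid voxels per axis), and the accumulated
    displacement receives a light elastic smoothing.  The displacement is
    estimated in fixed-grid voxel units, which balances the step sizes
    between fine in-plane and coarse through-plane axes on anisotropic
    grids.  Returns the *total* displacement field (affine composed with the
    free deformation) on the fixed grid, as a point map standard ->
    individual.

    Larger ``reg_weight`` gives a stiffer deformation; the estimate is
    deterministic.
    """
    _check_nondegenerate(moving, fixed)
    A = init.matrix if init is not None else np.eye(4)
    if grid_spacing is None:
        spacing_vox = 2.0 * np.ones(3)
    else:
        spacing_mm = np.broadcast_to(np.asarray(grid_spacing, float), (3,))
        spacing_vox = spacing_mm / fixed.voxel_size
    scale = float(np.std(fixed.data))

    u: np.ndarray | None = None  # pre-affine displacement, fixed-grid voxel units
    n_levels = len(iterations)
    factors = [2 ** (n_levels - 1 - i) for i in range(n_levels)]
    prev_fac: tuple[int, ...] | None = None
    for f, n_it in zip(factors, iterations):
        fac = _level_factors(fixed.shape, f)
        fixed_l = _decimate(fixed, fac)
        moving_l = _decimate(moving, _level_factors(moving.shape, f))
        if u is None:
            u = np.zeros(fixed_l.shape + (3,))
        elif u.shape[:3] != fixed_l.shape:
            zf = [t / s for t, s in zip(fixed_l.shape, u.shape[:3])]
            ratio = np.array(prev_fac, float) / np.array(fac, float)
            u = np.stack(
                [
                    ndimage.zoom(u[..., c], zf, order=1, mode="nearest") * ratio[c]
                    for c in range(3)
                ],
                axis=-1,
            )
        prev_fac = fac
        idx = np.indices(fixed_l.shape, dtype=float).reshape(3, -1)
        Afix = fixed_l.affine
        inv_mov = np.linalg.inv(moving_l.affine)
        fvals = fixed_l.data.ravel().astype(float) / scale
        sigma_up = spacing_vox * reg_weight
        for _ in range(n_it):
            uf = u.reshape(-1, 3).T
            Xu = Afix[:3, :3] @ (idx + uf) + Afix[:3, 3:4]
            cur = A[:3, :3] @ Xu + A[:3, 3:4]
            vox = snap_to_edges(inv_mov[:3, :3] @ cur + inv_mov[:3, 3:4],
                                moving_l.shape)
            warped = ndimage.map_coordinates(
                moving_l.data.astype(float), vox, order=1, mode="constant", cval=0.0
            ) / scale
            if not np.isfinite(warped).all():  # pragma: no cover
                raise RegistrationError("non-finite metric during optimization")
            diff = warped - fvals
            g = np.stack(
                [gg.ravel() for gg in np.gradient(warped.reshape(fixed_l.shape))]
            )
            denom = (g * g).sum(axis=0) + diff * diff + 1e-12
            force = np.clip(-diff * g / denom, -1.0, 1.0).T.reshape(u.shape)
            for c in range(3):
                force[..., c] = ndimage.gaussian_filter(
                    force[..., c], sigma_up, mode="nearest"
                )
            u = u + force
            for c in range(3):  # light elastic pass keeps the field coherent
                u[..., c] = ndimage.gaussian_filter(u[..., c], 0.5, mode="nearest")

    assert u is not None
    idx = np.indices(fixed.shape, dtype=float).reshape(3, -1)
    uf = u.reshape(-1, 3).T
    X0 = fixed.affine[:3, :3] @ idx + fixed.affine[:3, 3:4]
    Xu = fixed.affine[:3, :3] @ (idx + uf) + fixed.affine[:3, 3:4]
    total = A[:3, :3] @ Xu + A[:3, 3:4] - X0
    disp = total.T.reshape(fixed.shape + (3,))
    return DeformationField(disp, fixed.affine.copy())


# ---------------------------------------------------------------------------
# Diffeomorphic (TPM path)
# ---------------------------------------------------------------------------

def exponentiate_velocity(vel: DeformationField, n_squarings: int = 6) -> DeformationField:
    """Exponential of a stationary velocity field by scaling and squaring.

    The velocity is divided by ``2**n_squarings`` and the resulting small
    displacement self-composed that many times, approximating the time-1 flow
    of ``dx/dt = v(x)``.
    """
    w = vel.displacement / (2.0 ** n_squarings)
    affine = vel.affine.copy()
    shape = vel.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    X = affine[:3, :3] @ idx + affine[:3, 3:4]
    for _ in range(n_squarings):
        fld = DeformationField(w, affine)
        wf = w.reshape(-1, 3).T
        w = (wf + fld.sample_displacement(X + wf)).T.reshape(w.shape)
    return DeformationField(w, affine)


def integrate_velocity_euler(vel: DeformationField, n_steps: int = 64) -> DeformationField:
    """Explicit Euler integration of the same flow (independent slow path)."""
    affine = vel.affine.copy()
    idx = np.indices(vel.shape, dtype=float).reshape(3, -1)
    X = affine[:3, :3] @ idx + affine[:3, 3:4]
    y = X.copy()
    for _ in range(n_steps):
        y = y + vel.sample_displacement(y) / n_steps
    return DeformationField((y - X).T.reshape(vel.shape + (3,)), affine)


def register_diffeomorphic(
    moving_tpms: list[Volume3D],
    fixed_tpms: list[Volume3D],
    n_steps: int = 6,
    reg_sigma_vox: float = 2.0,
    iterations: tuple[int, ...] = (30, 15),
    return_velocity: bool = False,
) -> DeformationField | tuple[DeformationField, DeformationField]:
    """Diffeomorphic registration of tissue probability maps.

    Estimates a stationary velocity field minimizing the multi-channel
    sum-of-squares between the fixed TPMs and the warped moving TPMs, and
    returns its exponential (scaling-and-squaring with ``n_steps``
    squarings) — a displacement field on the fixed grid with positive
    Jacobian determinant, mapping standard -> individual points.
    """
    if len(moving_tpms) != len(fixed_tpms) or not moving_tpms:
        raise ValueError("moving and fixed TPM lists must be equal length and nonempty")
    for t in list(moving_tpms) + list(fixed_tpms):
        if t.data.min() < -1e-6 or t.data.max() > 1 + 1e-6:
            raise ValueError("TPM values must lie in [0, 1]")
    fixed0 = fixed_tpms[0]

    v: np.ndarray | None = None  # velocity (mm) on fixed level grid
    n_levels = len(iterations)
    factors = [2 ** (n_levels - 1 - i) for i in range(n_levels)]
    for f, n_it in zip(factors, iterations):
        fac = _level_factors(fixed0.shape, f)
        fx = [_decimate(t, fac) for t in fixed_tpms]
        mv = [_decimate(t, _level_factors(t.shape, f)) for t in moving_tpms]
        if v is None:
            v = np.zeros(fx[0].shape + (3,))
        elif v.shape[:3] != fx[0].shape:
            zf = [t / s for t, s in zip(fx[0].shape, v.shape[:3])]
            v = np.stack(
                [ndimage.zoom(v[..., c], zf, order=1, mode="nearest") for c in range(3)],
                axis=-1,
            )
        affine_l = fx[0].affine
        X = fx[0].world_grid()
        sigma = reg_sigma_vox * np.ones(3)
        cap = float(fx[0].voxel_size.max())
        for _ in range(n_it):
            d = exponentiate_velocity(DeformationField(v, affine_l), n_steps)
            cur = X + d.displacement.reshape(-1, 3).T
            force = np.zeros_like(X)
            for fch, mch in zip(fx, mv):
                vox = snap_to_edges(mch.world_to_voxel(cur), mch.shape)
                warped = ndimage.map_coordinates(
                    mch.data.astype(float), vox, order=1, mode="constant", cval=0.0
                )
                gw = _world_gradient(warped.reshape(fch.shape), affine_l)
                force += _demons_force(
                    fch.data.ravel().astype(float), warped, gw, 1.0
                )
            force = np.clip(force / len(fx), -cap, cap)
            v = v + force.T.reshape(v.shape)
            for c in range(3):
                v[..., c] = ndimage.gaussian_filter(v[..., c], sigma, mode="nearest")

    assert v is not None
    vel = DeformationField(v, fixed0.affine.copy())
    disp = exponentiate_velocity(vel, n_steps)
    if return_velocity:
        return disp, vel
    return disp


# ---------------------------------------------------------------------------
# Series realignment and spatial normalization
# ---------------------------------------------------------------------------

def realign_series(
    series: Series4D, degree: int = 3
) -> tuple[Series4D, Volume3D, list[RigidParams]]:
    """Rigidly realign a 4D series to its first volume and average it.

    Head motion between repetitions is removed by 6-parameter least-squares
    rigid registration of every volume to the first; the mean image over the
    realigned volumes is the anatomical reference used for parcellation.
    """
    if len(series) == 1:
        v = series.volumes[0]
        return series, v.with_data(v.data.astype(float)), [RigidParams.identity()]
    ref = series.volumes[0]
    realigned = [ref.with_data(ref.data.astype(float))]
    params = [RigidParams.identity()]
    for vol in series.volumes[1:]:
        if float(np.std(vol.data)) == 0.0 or float(np.std(ref.data)) == 0.0:
            # featureless volumes carry no motion information; keep them put
            realigned.append(vol.with_data(vol.data.astype(float)))
            params.append(RigidParams.identity())
            continue
        t, rp = register_rigid(vol, ref)
        mapping = world_map_to_voxel_mapping(ref.affine, vol.affine, t.apply)
        realigned.append(
            resample(vol, mapping, degree=degree, out_shape=ref.shape,
                     out_affine=ref.affine)
        )
        params.append(rp)
    mean = ref.with_data(np.mean([v.data for v in realigned], axis=0))
    return Series4D(realigned, list(series.times)), mean, params


def normalize_image(
    v: Volume3D,
    transform: Transform,
    out_voxel: Sequence[float] | None = None,
    like: Volume3D | None = None,
    degree: int = 4,
) -> Volume3D:
    """Resample an individual image into standard space.

    ``transform`` is the standard -> individual point map from registration.
    The output grid is taken from ``like`` (typically the template), resliced
    to ``out_voxel`` mm if requested; without ``like`` the input's own field
    of view is used.
    """
    base = like if like is not None else v
    out_affine = base.affine.copy()
    out_shape = base.shape
    if out_voxel is not None:
        out_voxel = np.asarray(out_voxel, dtype=float)
        if (out_voxel <= 0).any():
            raise ValueError("output voxel sizes must be positive")
        old_voxel = base.voxel_size
        direction = base.affine[:3, :3] / old_voxel
        new_A3 = direction * out_voxel
        # keep the world position of the (-0.5,-0.5,-0.5) grid corner fixed
        corner = base.affine[:3, :3] @ (-0.5 * np.ones(3)) + base.affine[:3, 3]
        out_affine = np.eye(4)
        out_affine[:3, :3] = new_A3
        out_affine[:3, 3] = corner - new_A3 @ (-0.5 * np.ones(3))
        out_shape = tuple(
            int(np.ceil(s * ov / nv))
            for s, ov, nv in zip(base.shape, old_voxel, out_voxel)
        )
    mapping = world_map_to_voxel_mapping(out_affine, v.affine, transform.apply)
    return resample(v, mapping, degree=degree, out_shape=out_shape,
                    out_affine=out_affine)
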