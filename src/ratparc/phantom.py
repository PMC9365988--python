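"""Synthetic phantom generator: template, atlas, TPMs, deformed "individual"
images and MEMRI-like 4D series with ground-truth transforms.

The phantom stands in for a rodent MEMRI study: an ellipsoidal "brain" inside
a dark background, partitioned into compact functional regions (a Voronoi
tessellation of seeded points), imaged at anisotropic voxel sizes echoing
thick-slice MEMRI acquisitions.  Each "individual" is the template warped by
an analytic, separable sinusoidal diffeomorphism — chosen because its
invertibility has a closed-form bound (amplitude * 2π / wavelength < 1) and
because the truth field is written down independently of any registration
code it is later used to test.  Enhancement mimics Mn²⁺ accumulation: chosen
regions are brighter by a contrast factor that decays geometrically across
repetitions.

All generators are bit-reproducible given a PhantomSpec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .image_core import BinaryMask, LabelAtlas, Series4D, Volume3D, resample
from .transforms import DeformationField, InverseDeformation, invert_deformation

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "make_template",
    "make_individual",
    "make_memri_series",
    "make_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic subject.

    Defaults echo a thick-slice rodent MEMRI acquisition: a 64x64x24 grid at
    0.14 x 0.14 x 1.2 mm, 66 functional regions, a smooth sinusoidal
    inter-individual deformation of 2-voxel amplitude, additive Gaussian
    noise at 5% of mean brain intensity, two Mn²⁺-enhanced regions at 5x
    contrast whose signal decays 10% per repetition over six repetitions.
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (0.14, 0.14, 1.2)
    n_rois: int = 66
    deformation_type: str = "sinusoidal"  # or "polynomial-affine"
    amplitude: float = 2.0  # voxels
    wavelength: float = 20.0  # voxels
    noise_sd: float = 0.05  # fraction of mean brain intensity
    enhancement_rois: tuple[int, ...] = (1, 2)
    contrast: float = 5.0
    decay_rate: float = 0.1  # fractional signal decrease per volume
    n_volumes: int = 6
    base_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.decay_rate < 1):
            raise ValueError("decay_rate must lie in [0, 1)")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if self.deformation_type not in ("sinusoidal", "polynomial-affine"):
            raise ValueError("deformation_type must be sinusoidal or polynomial-affine")


def _rngs(spec: PhantomSpec) -> list[np.random.Generator]:
    """Three independent deterministic streams: template, individual, series."""
    children = np.random.SeedSequence(spec.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _base_affine(spec: PhantomSpec) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spec.voxel_size)
    center = (np.array(spec.shape, dtype=float) - 1) / 2.0
    A[:3, 3] = -A[:3, :3] @ center
    return A


# ---------------------------------------------------------------------------
# Template, atlas, TPMs
# ---------------------------------------------------------------------------

def make_template(
    spec: PhantomSpec,
) -> tuple[Volume3D, LabelAtlas, list[Volume3D], BinaryMask]:
    """Ellipsoidal brain-like template with a Voronoi region atlas.

    Regions are mutually exclusive, compact and contiguous (Voronoi cells of
    seed points drawn inside the ellipsoid); each carries a distinct mean
    intensity, lightly smoothed, so registration has structure to lock onto.
    TPMs are two classes (tissue, background) as smoothed indicators summing
    to 1.  Deterministic per seed.
    """
    rng = _rngs(spec)[0]
    shape = spec.shape
    affine = _base_affine(spec)
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1) / 2.0
    radii = 0.42 * np.array(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    brain = r2 <= 1.0
    interior = np.argwhere(brain)
    if spec.n_rois > len(interior):
        raise ValueError(
            f"n_rois={spec.n_rois} exceeds the {len(interior)} interior voxels"
        )

    pick = rng.choice(len(interior), size=spec.n_rois, replace=False)
    seeds = interior[pick].astype(float)
    # Voronoi assignment of brain voxels to the nearest seed, in physical mm:
    # regions compact in world space stay wide in-plane at thick slices
    vs = np.array(spec.voxel_size)
    d = cdist(interior.astype(float) * vs, seeds * vs)
    assign = d.argmin(axis=1) + 1
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(interior.T)] = assign

    roi_intensity = rng.uniform(0.7, 1.3, size=spec.n_rois)
    template = np.zeros(shape, dtype=float)
    template[brain] = spec.base_intensity * roi_intensity[assign - 1]
    template = ndimage.gaussian_filter(template, sigma=(0.8, 0.8, 0.4))

    tissue = np.clip(
        ndimage.gaussian_filter(brain.astype(float), sigma=1.0), 0.0, 1.0
    )
    tpms = [
        Volume3D(tissue, affine.copy()),
        Volume3D(1.0 - tissue, affine.copy()),
    ]
    lut = {i + 1: f"roi_{i + 1:03d}" for i in range(spec.n_rois)}
    atlas = LabelAtlas(Volume3D(labels, affine.copy()), lut)
    mask = BinaryMask(Volume3D(brain.astype(np.uint8), affine.copy()))
    return Volume3D(template, affine.copy()), atlas, tpms, mask


# ---------------------------------------------------------------------------
# Ground-truth deformation and the individual image
# ---------------------------------------------------------------------------

def _displacement_voxels(spec: PhantomSpec, vox: np.ndarray) -> np.ndarray:
    """Analytic displacement (voxels) at (3, N) voxel coordinates.

    Sinusoidal: cyclic separable components d_x(y), d_y(z), d_z(x); the
    Jacobian of x -> x + d is I plus a nilpotent-patterned matrix whose
    determinant is 1 - (A*2π/λ)³cos·cos·cos, positive whenever
    A*2π/λ < 1.  Polynomial-affine: a gentle global scale-plus-shift whose
    maximum displacement is ~``amplitude`` voxels.
    """
    A, lam = spec.amplitude, spec.wavelength
    if spec.deformation_type == "sinusoidal":
        k = 2.0 * np.pi / lam
        d = np.empty_like(vox)
        d[0] = A * np.sin(k * vox[1])
        d[1] = A * np.sin(k * vox[2])
        d[2] = A * np.sin(k * vox[0])
        return d
    # polynomial-affine
    center = (np.array(spec.shape, dtype=float)[:, None] - 1) / 2.0
    s = A / max(spec.shape)
    return s * (vox - center) + A / 2.0


def truth_field(spec: PhantomSpec, affine: np.ndarray) -> DeformationField:
    """Analytic individual -> standard point map as a DeformationField in mm."""
    idx = np.indices(spec.shape, dtype=float).reshape(3, -1)
    d_vox = _displacement_voxels(spec, idx)
    d_mm = affine[:3, :3] @ d_vox
    return DeformationField(d_mm.T.reshape(spec.shape + (3,)), affine.copy())


def make_individual(
    template: Volume3D,
    brain_mask: BinaryMask,
    spec: PhantomSpec,
) -> tuple[Volume3D, DeformationField]:
    """Warp the template by the analytic field and add Gaussian noise.

    Returns the individual image and the analytic truth map (individual ->
    standard space); the numerically verified inverse is available from
    :attr:`PhantomBundle.truth_forward`.
    """
    if spec.deformation_type == "sinusoidal":
        bound = spec.amplitude * 2.0 * np.pi / spec.wavelength
        if bound >= 1.0:
            raise ValueError(
                f"amplitude*2π/wavelength = {bound:.3f} >= 1 breaks diffeomorphism"
            )
    rng = _rngs(spec)[1]
    fld = truth_field(spec, template.affine)

    def mapping(out_vox: np.ndarray) -> np.ndarray:
        return out_vox + _displacement_voxels(spec, out_vox)

    warped = resample(template, mapping, degree=3, out_shape=spec.shape,
                      out_affine=template.affine)
    brain_mean = float(template.data[brain_mask.array > 0].mean())
    noise = spec.noise_sd * brain_mean
    data = warped.data + (rng.normal(0.0, noise, size=spec.shape) if noise else 0.0)
    return Volume3D(data, template.affine.copy()), fld


# ---------------------------------------------------------------------------
# MEMRI series
# ---------------------------------------------------------------------------

def make_memri_series(
    individual: Volume3D,
    atlas_individual: LabelAtlas,
    spec: PhantomSpec,
) -> Series4D:
    """Enhancement-and-decay MEMRI series in individual space.

    Volume ``k`` has intensity ``base * contrast * (1 - decay_rate)**k`` in
    the enhanced regions and ``base`` elsewhere inside the brain, plus
    Gaussian noise; the geometry comes from the individual-space label image.
    """
    labels = atlas_individual.labels.data
    present = set(atlas_individual.indices)
    for roi in spec.enhancement_rois:
        if roi not in present:
            raise ValueError(f"enhancement ROI {roi} not present in the atlas")
    rng = _rngs(spec)[2]
    support = labels > 0
    enhanced = np.isin(labels, spec.enhancement_rois)
    base = np.where(support, spec.base_intensity, 0.0)
    noise = spec.noise_sd * spec.base_intensity
    vols = []
    for k in range(spec.n_volumes):
        level = spec.contrast * (1.0 - spec.decay_rate) ** k
        data = base * np.where(enhanced, level, 1.0)
        if noise:
            data = data + rng.normal(0.0, noise, size=spec.shape)
        vols.append(Volume3D(data, individual.affine.copy()))
    return Series4D(vols)


# ---------------------------------------------------------------------------
# Bundles and cohorts
# ---------------------------------------------------------------------------

@dataclass
class PhantomBundle:
    """Everything one synthetic subject provides, with ground truth attached."""

    spec: PhantomSpec
    template: Volume3D
    atlas: LabelAtlas
    tpms: list[Volume3D]
    brain_mask: BinaryMask  # template-space support
    individual: Volume3D
    truth_inverse: DeformationField  # analytic: individual -> standard
    individual_tpms: list[Volume3D]
    truth_individual_labels: LabelAtlas  # atlas warped to individual space (NN)
    series: Series4D
    group: str = ""

    @cached_property
    def truth_forward(self) -> InverseDeformation:
        """Numerical inverse of the analytic field: standard -> individual.

        This is the map a successful registration should recover; its
        composition residual with the analytic field is below 0.01 voxel.
        """
        return invert_deformation(self.truth_inverse, tol=0.005, max_iter=100)

    @property
    def truth_individual_brain(self) -> BinaryMask:
        """Brain support in individual space (nonzero warped labels)."""
        return BinaryMask(
            self.truth_individual_labels.labels.with_data(
                (self.truth_individual_labels.labels.data > 0).astype(np.uint8)
            )
        )


def _warp_to_individual(vol: Volume3D, spec: PhantomSpec, degree: int) -> Volume3D:
    def mapping(out_vox: np.ndarray) -> np.ndarray:
        return out_vox + _displacement_voxels(spec, out_vox)

    return resample(vol, mapping, degree=degree, out_shape=spec.shape,
                    out_affine=vol.affine)


def make_phantom(spec: PhantomSpec | None = None, **overrides) -> PhantomBundle:
    """Generate one complete synthetic subject from a spec (or keyword overrides)."""
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    template, atlas, tpms, mask = make_template(spec)
    individual, fld = make_individual(template, mask, spec)
    ind_labels = _warp_to_individual(
        atlas.labels.with_data(atlas.labels.data.astype(float)), spec, degree=0
    )
    ind_atlas = LabelAtlas(
        ind_labels.with_data(np.round(ind_labels.data).astype(np.int32)),
        dict(atlas.lut),
    )
    ind_tpms = [
        Volume3D(np.clip(_warp_to_individual(t, spec, degree=1).data, 0, 1), t.affine.copy())
        for t in tpms
    ]
    series = make_memri_series(individual, ind_atlas, spec)
    return PhantomBundle(
        spec=spec,
        template=template,
        atlas=atlas,
        tpms=tpms,
        brain_mask=mask,
        individual=individual,
        truth_inverse=fld,
        individual_tpms=ind_tpms,
        truth_individual_labels=ind_atlas,
        series=series,
    )


def make_cohort(
    n_healthy: int = 5,
    n_model: int = 10,
    effect: float = 0.5,
    spec: PhantomSpec | None = None,
) -> list[PhantomBundle]:
    """A case-control cohort: healthy subjects first, then model subjects.

    Model subjects have their enhanced-region contrast multiplied by
    ``1 - effect`` (a fractional signal reduction, as after a lesion that
    lowers Mn²⁺ uptake).  Per-subject seeds are spawned deterministically
    from the master seed in ``spec.seed``.
    """
    if not (0.0 <= effect < 1.0):
        raise ValueError("effect must lie in [0, 1)")
    if spec is None:
        spec = PhantomSpec()
    children = np.random.SeedSequence(spec.seed).spawn(n_healthy + n_model)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    bundles = []
    for i in range(n_healthy):
        s = replace(spec, seed=seeds[i])
        b = make_phantom(s)
        b.group = "healthy"
        bundles.append(b)
    model_contrast = spec.contrast * (1.0 - effect)
    for i in range(n_model):
        s = replace(spec, seed=seeds[n_healthy + i], contrast=model_contrast)
        b = make_phantom(s)
        b.group = "model"
        bundles.append(b)
    return bundles
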