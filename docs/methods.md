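# Methods

## The problem

Region-of-interest (ROI) analysis of rodent brain MRI — in particular
manganese-enhanced MRI (MEMRI), where Mn²⁺ uptake makes active neurons
bright — conventionally normalizes every individual image into a standard
stereotaxic space (Paxinos space for the rat) and reads ROI statistics off a
shared atlas.  Spatial normalization resamples the individual image, and
interpolation blends the sparse, subtle enhanced voxels with their
un-enhanced neighbours: the extracted ROI signal is biased downward and
case–control contrasts lose power.  `ratparc` implements the converse
strategy: leave the individual image untouched and bring the atlas to it.

## The parcellation procedure

1. **Registration (individual → standard).**  Either of two paths estimates
   the normalization transform, represented throughout as a *point map from
   standard space to individual space* (the map that resamples the
   individual onto the standard grid — the operational content of an SPM
   `Matrix_sn`/`Deform_y`):
   * *template path*: 12-parameter affine registration to an intensity
     template (normalized cross-correlation, Powell search over a 3-level
     Gaussian pyramid; mutual information available for cross-modality),
     optionally refined by an intensity-driven nonlinear step;
   * *TPM path*: diffeomorphic registration of tissue probability maps by a
     stationary velocity field whose exponential is computed by
     scaling-and-squaring (6 squarings by default), guaranteeing a positive
     Jacobian.
   A 4D MEMRI series is first rigidly realigned to its first volume and
   averaged; the mean image is what gets registered.
2. **Inversion.**  Affine transforms invert exactly.  Deformation fields are
   inverted by a damped fixed-point iteration `e ← −d(x + e)` evaluated on
   the individual grid (where the masks will live), with under-relaxation on
   oscillation; the achieved composition residual is recorded on the result
   and a residual above 10× the tolerance (default 0.01 voxel) is an error.
3. **Atlas splitting.**  Every atlas region becomes its own {0,1} mask
   image, so that neighbouring labels cannot bleed into each other during
   interpolation.
4. **Warping, thresholding, refinement.**  Each binary mask is pulled onto
   the individual grid through the inverse map with degree-4 B-spline
   interpolation (samples are prefiltered to spline coefficients, so this is
   true interpolation).  The continuous membership image is thresholded at
   0.5 and the contour polished by morphological opening with a one-voxel
   structuring element.
5. **Recombination.**  Refined regions are re-indexed and merged.  A voxel
   claimed by several regions goes to the highest fuzzy membership; exact
   ties go to the smaller region, then to the lower index — deterministic
   and order-independent.  Gaps opened by the refinement remain background
   and are reported, never in-filled.

Evaluation utilities compute the Dice coefficient 2|A∩B|/(|A|+|B|) between
binary masks (whole-brain masks come from an Otsu threshold, largest
connected component, hole fill), per-volume ROI mean time courses in
individual vs normalized space, and pooled- or Welch-variance two-sample
t-tests (significance threshold 0.05).

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| interpolation degree | 4 | B-spline degree for mask warping and normalization; "4th-degree" follows the SPM menu convention (degree, not order). 0/1/3 available. |
| binarization threshold | 0.5 | membership level at which a warped mask voxel counts as inside; the half-level surface of an interpolated indicator tracks the true boundary to ≈ half a voxel. |
| opening element | `disc2D`, radius 1 | city-block disc applied slice-wise in-plane. Rodent MEMRI slices (~1.2 mm) are an order of magnitude thicker than the in-plane voxel (~0.14 mm); a 3D ball (`ball3D`, available by flag) erases structures one slice thick. |
| inversion tolerance | 0.01 voxel | fixed-point stopping rule; max 100 iterations (the under-relaxed iteration contracts at ~0.875/step on strong fields). |
| nonlinear regularization | kernel 2 voxels, `reg_weight` 1 | the demons-style update is smoothed with a Gaussian of `grid_spacing × reg_weight` (fluid regularization) plus a light (0.5 voxel) elastic pass on the accumulated field. Larger `reg_weight` gives a stiffer, smaller deformation. |
| `n_steps` (squarings) | 6 | velocity-field exponential resolution; agrees with 64-step Euler integration to < 0.05 voxel on test fields. |
| voxel zoom | ×10 (`scale_voxels`) | rodent heads are mm-scale; enlarging the world geometry tenfold before normalization matches tooling calibrated for human heads. Pure similarity of world space, data untouched. |

Design choices worth recording: the nonlinear template-path refinement is a
Gaussian-regularized demons-type scheme rather than an explicit B-spline
control grid — the same small-deformation class with fewer moving parts, and
its displacement is estimated in fixed-grid *voxel* units so that the fine
in-plane and coarse through-plane axes take balanced steps on anisotropic
grids.  Regularizing the *accumulated* field instead would attenuate a
recovered displacement of wavenumber k by exp(−k²σ²/2) every iteration and
the warp would never build up.  `set_origin` takes the landmark (e.g. the
dorsal third ventricle) as a voxel coordinate, which makes the operation
idempotent; a world-mm form is available.  Refinement happens before overlap
resolution; overlap resolution only removes voxels, so per-label counts
never exceed the refined-mask counts.

## The synthetic phantom

No animal data ship with the package; every test and the acceptance script
run on a generated phantom designed to echo a thick-slice rodent MEMRI
study:

* 64×64×24 grid at 0.14×0.14×1.2 mm (anisotropy ≈ 8.6), an ellipsoidal
  "brain" occupying ~42% of each dimension;
* 66 functional regions by default: a Voronoi partition of seed points drawn
  inside the ellipsoid, with distances measured in **physical mm** so that
  regions are compact in world space — a few mm across, hence several slices
  thick and wide in-plane, like real anatomical ROIs at thick slices;
* per-region intensities (uniform 0.7–1.3 of the base level, lightly
  smoothed) give registration gradients to lock onto; two-class tissue /
  background probability maps are smoothed indicators summing to 1;
* the "individual" is the template warped by a separable sinusoidal
  displacement (components d_x(y), d_y(z), d_z(x); amplitude 2 voxels per
  axis, wavelength 20 voxels) plus Gaussian noise at 5% of mean brain
  intensity.  The cyclic component structure makes the Jacobian determinant
  1 − (2πA/λ)³·cos·cos·cos, so amplitude·2π/wavelength < 1 is an exact
  diffeomorphism bound, enforced at generation;
* the analytic field is the ground-truth individual→standard map (it renders
  the individual); its numerically verified inverse (composition residual
  < 0.01 voxel) is what a perfect registration would output, and lets every
  downstream stage be tested with registration bypassed;
* the MEMRI series assigns enhanced regions the intensity
  base·contrast·(1−decay)^k at repetition k (contrast 5, decay 0.1, six
  repetitions) and base elsewhere in the brain, plus noise;
* cohorts spawn per-subject seeds from a master seed; "model" subjects have
  their enhancement contrast multiplied by (1 − effect).

What the phantom does **not** model: Rician MRI noise (noise is additive
Gaussian), intensity bias fields, partial-volume mixtures at tissue
boundaries, anatomically realistic region shapes, or Mn²⁺ pharmacokinetics.
Passing tests therefore demonstrate the correctness of the geometric and
statistical machinery under controlled deformations and noise — not
performance on scanner data, where registration quality is the binding
constraint.

## Problem sizes used by the tests

The full-pipeline overlap gate runs at the default 64×64×24 / 66-ROI
conditions.  Known-warp per-ROI recovery and identity-pipeline checks use
8-region phantoms on the same grid: at 66 regions on a desk-scale grid each
region is ~8 voxels across and the opening alone costs ~10% Dice for any
implementation, which would test the grid resolution rather than the
machinery.  Repeated-simulation checks (individual- vs standard-space signal
dominance; cohort power and null calibration, 100 replicates each) run on
32×32×12 grids with 6 regions, which preserves the contrast, noise, effect
size and group sizes those checks are about.

## Known limitations

* The template-path nonlinear step recovers boundaries well but leaves flat
  region interiors under-constrained (no intensity gradient, as for any
  intensity-driven method); whole-brain and boundary measures are the
  meaningful quality metrics.
* The TPM path registers two-class probability maps; with only a
  tissue/background split it effectively constrains the brain outline, not
  internal anatomy.  Richer map sets improve it.
* Images whose anatomy is destroyed (tumour, infarct) violate the
  registration model; the method is not intended for them.
* Field inversion assumes the forward field is fold-free; a folded input
  surfaces as a convergence error naming the worst voxel.
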