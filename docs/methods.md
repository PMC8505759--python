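# Methods

## Overview

`truenet` segments white matter hyperintensities (WMH) from co-registered,
brain-extracted FLAIR and T1-weighted volumes with a *triplanar ensemble* of
three independent, shallow 2D U-Nets — one per anatomical plane (axial,
sagittal, coronal).  Each network scores its own slice stack; the per-slice
probability maps are reassembled into 3D maps at the original volume
dimensions and averaged voxel-wise.  The averaged map is restricted to a
white-matter inclusion mask and thresholded at 0.5 to give the final binary
lesion map.  Training uses a composite objective — cross-entropy weighted by
an anatomical distance map plus a Dice term — designed to keep sensitivity
high in the deep white matter, where lesions are small, punctate and
massively outnumbered by background voxels.

The package also ships a synthetic brain-phantom generator so that the whole
pipeline (preprocessing, weight maps, training, ensemble inference,
post-processing, evaluation) runs end to end on one CPU in minutes, with
exact ground truth for every stage.

## Model

Each plane network is a U-Net trimmed to 3 resolution levels: two
(conv → batch-norm → ReLU) blocks per level, 2×2 max-pool downsampling, 2×2
transposed-convolution upsampling, skip concatenations, and a final 1×1
convolution producing two-class logits (softmax applied at the
loss/inference boundary).  Convolutions are 3×3 except the first layer of
the sagittal and coronal networks, which uses 5×5 kernels (a larger first
receptive field reduces cross-slice discontinuities in those planes).
Channel widths double per level from `base_channels` (64 at production
scale; 4 in the desk-scale experiments).  The three plane networks never
share parameters and are trained independently.

Baselines for the model-dimension comparison: a single-plane (axial-only)
2D U-Net, and a volumetric 3D U-Net.  The 3D baseline follows the *classic*
3D U-Net layout with 4 resolution levels; the depth-trimming to 3 levels is
specific to the 2D plane networks.  This matters for the parameter-count
comparison: three trimmed 2D nets with 3×3 kernels carry essentially the
same convolutional weight count as one equally-trimmed 3D net with 3×3×3
kernels (27 = 3 × 9), so the triplanar ensemble is only smaller than the 3D
model when the 3D model is the standard, deeper architecture — which is
what "3D U-Net" denotes in the field.  The parameter-count test compares
against that standard baseline by direct counting.

The network layer library (convolution, batch normalisation, max-pooling,
transposed convolution, Adam) is implemented in numpy with hand-derived
backward passes; convolutions run as im2col + BLAS matrix products, and all
gradients are verified against central finite differences in the test
suite.

## Loss

For softmax probabilities `p`, one-hot labels `y` and the spatial weight
map `D_wei`, the training objective is

    L = CE + DcL
    CE  = (1 / N) * Σ_x Σ_i y_i(x) · D_wei(x) · (−log p_i(x))
    DcL = −2 |M ∩ P| / (|M| + |P|)            ∈ [−1, 0]

with equal (unit) weights on the two terms.  Numerical choices:

- The printed Dice uses the thresholded binary prediction, which has no
  gradient; training uses the *soft* Dice (WMH-channel probabilities in
  place of the binary map); the hard variant is available for monitoring.
- CE is averaged over the voxels of the batch so loss magnitudes are
  independent of batch and slice size.
- `log` is clamped at 1e-7.  The Dice denominator is used exactly; when
  both masks are empty the Dice loss is defined as −1 (perfect agreement).
- Four ablation arms are supported: plain CE, weighted CE, weighted CE +
  Dice (the default), Dice only.

## Spatial weight maps

`D_wei = D_vent + D_GM`, both Euclidean distances in mm computed with an
exact distance transform honouring anisotropic voxel sizes: `D_vent` is the
distance from the ventricle mask (zero on ventricles, maximum `N_D` inside
the brain mask) and `D_GM` the distance from the cortical grey-matter
ribbon (zero on GM, growing toward the brain centre, maximum `M_D`).  Their
sum peaks in the deep white matter, so the weighted CE penalises deep false
negatives more than periventricular ones.  The weights depend only on the
anatomy masks and voxel sizes — never on intensities or lesions — and are
applied raw, in mm (an optional scale factor exists but defaults to 1).
The GM distance is taken from the full GM ribbon; distance from the ribbon
boundary only is available via `gm_boundary_only`.

## Preprocessing and slice geometry

Volumes are stored in a canonical (x, y, z) = (sagittal-, coronal-,
axial-normal) axis order; NIfTI inputs are reoriented to the closest
canonical form on load.  Intensities are z-scored within the brain mask
("Gaussian normalisation"; mean 0, SD 1 in-mask, zeros outside), then the
field of view is cropped to the brain-mask bounding box plus a 2-voxel pad
(the crop record makes this exactly invertible).

Per-plane in-plane sizes are fixed: axial 128×192 (by centre crop/pad only,
no interpolation), sagittal 192×120 and coronal 128×80 (by bilinear
resize; aspect is stretched, not padded).  Labels resample with
nearest-neighbour, probabilities and weight maps bilinearly.  Probability
maps are resized back to the pre-crop dimensions, zero-padded outside the
crop, and clipped to [0, 1].  The desk-scale experiments use reduced target
sizes (axial 64×64, sagittal/coronal 64×24) matched to the phantom FOV; the
resize machinery is identical.

## Post-processing

The ensemble probability map is the voxel-wise mean of the three plane maps
(accumulated in float64 so plane order cannot perturb the float32 result).
The white-matter inclusion mask is `brain \ (dilate(cortical CSF) ∪
ventricles ∪ deep-GM exclusions)`; the CSF dilation radius is metric
(default 2 mm).  The final map is `(masked probability ≥ 0.5)` — ties count
as lesion, for bit-exact reproducibility.

## Training recipe

Adam (ε = 1e-4), batch size 8, initial learning rate 1e-3 decayed by 0.1
every 2 epochs to a floor of 1e-5; subject-wise 90/10 train/validation
split; early stopping after 20 epochs without a strict validation-loss
improvement (> 1e-6), restoring the best-validation checkpoint.
Augmentation applies one random combination per draw — translation
(x/y ∈ [−10, 10] voxels), rotation (θ ∈ [−10, 10]°), Gaussian noise
(σ² ∈ [0.01, 0.09]) and Gaussian blur (σ ∈ [0.1, 0.3]) — geometric
transforms shared by images, labels and weight maps; intensity transforms
on images only.  Axial slices are drawn 10× per epoch, sagittal/coronal 6×.

**Desk-scale calibration.**  The step-decay schedule is defined per epoch,
and an "epoch" at production scale is ~15,000 augmented slices (~1,900
optimiser steps).  A desk-scale epoch on a 10-phantom cohort is ~25× smaller,
so applying the decay every 2 such epochs would freeze the learning rate
after ~100 steps — a different optimisation trajectory, not a smaller one.
The demo therefore stretches the decay interval and sets per-plane epoch
budgets so each plane sees roughly 1,200–1,400 steps at 1e-3 (axial gets
more epochs because it has ~2.6× fewer slices per epoch than the
sagittal/coronal stacks on this phantom geometry), and augmentation draws
are reduced to 1× (the cohort's geometric diversity substitutes at this
problem size).  Paper-scale values remain the defaults of `TrainConfig` /
`AugmentConfig`; the scaled values live in `DEMO_ESTIMATOR_PARAMS` /
`ABLATION_SETTINGS` and are chosen once as the package's desk-scale study
conditions.  The loss ablation runs with a slightly tighter axial budget
(~1,100 steps at 1e-3): enough for a functional deep-region segmenter, but
short of the point where every loss arm converges on the phantom's
high-contrast lesions and the comparison washes out.

## Synthetic phantom

The phantom emulates a preprocessed anisotropic acquisition
(64×64×24 voxels at 1×1×3 mm by default): an ellipsoidal brain with an
outer 2 mm cortical-CSF shell, a 3 mm GM ribbon, WM interior and a central
ventricle cavity.  Periventricular lesions (default 2, radius 4–7 mm) are
spheres adjoining the ventricle surface — brighter, larger, confluent;
deep lesions (default 3, radius 2–3.5 mm) are small spheres placed so the
whole sphere lies beyond the 10 mm distance shell (mild clipping at the
outer WM edge only, ≥70 % of the sphere retained).  FLAIR contrast:
CSF 0.15 < WM 0.45 < GM 0.55 < deep lesion 0.80 < PV lesion 0.90; T1:
lesions (0.50–0.55) hypointense to WM (0.75).  Gaussian noise (SD 0.05) is
added inside the brain; at these settings lesions sit ~3 SD above WM after
normalisation, comparable in difficulty to a high-contrast FLAIR but
without the hard parts of real data (see limitations).  Cohorts jitter
lesion counts and radii deterministically from the cohort seed, spanning
low to high lesion loads.  Placement uses rejection sampling with a
1000-attempt cap and raises a geometry error when a spec is infeasible.

What the phantom does *not* model: bias fields, partial-volume effects at
tissue interfaces, diffuse lesion borders, anatomical variability, motion
or Gibbs artefacts.  Passing the end-to-end criteria on phantoms shows the
pipeline's plumbing, losses, geometry and optimisation work as specified —
not that the model reaches clinical-grade accuracy on real cohorts.

## Evaluation metrics

Dice similarity index (both-empty pairs defined as 1, empty-vs-nonempty
as 0); voxel-wise TPR and FPR (FPR over non-lesion voxels inside the brain
mask); cluster-wise TPR / precision / F1 with 26-connected clusters and
any-voxel overlap as the detection rule; absolute volume difference as a
percentage of the manual volume (mm³, error on an empty manual mask); and
H95 — the 95th percentile of the pooled symmetric set of boundary
closest-distances in mm (boundary = voxels with a face-neighbour outside
the mask; a directed variant is selectable; empty masks yield a missing
value).  The periventricular/deep split assigns voxels by the 10 mm
distance-from-ventricles rule (a straddling cluster contributes to both
compartments).  Rates whose denominator is empty are reported as missing,
never as zero.

## Known limitations

- The numpy network trains at small scale only; there is no GPU path, so
  production-size cohorts and 64-channel models are out of reach here.
- The phantom's high, stationary tissue contrast makes segmentation easier
  than clinical FLAIR; absolute metric values on phantoms should not be
  compared with values on real cohorts.
- The 3D baseline is exercised at reduced size; its production-scale
  behaviour is represented only by the parameter-count comparison.
- `run_ablation` supports leave-one-out evaluation, but the shipped
  experiments use a fixed split for runtime reasons.
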