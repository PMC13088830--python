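# Methods

## Scope and scale

The package implements a micro-CT-guided CBCT segmentation framework as a
fully testable pipeline. Real paired micro-CT/CBCT scans of extracted teeth
are not publicly available, so every experiment runs on synthetic phantoms
with analytically known ground truth. The phantoms are *miniature* teeth
(roots ≈ 2.4–3.4 mm, crowns ≈ 1.0–1.6 mm radius — roughly 40% of natural
linear scale) rendered at the *literal* scanner voxel sizes: 30 µm for the
micro-CT arm and 200 µm or 80 µm for the CBCT arm. This keeps micro-CT
grids at a few million voxels while preserving the quantity that governs
the segmentation problem: the ratio of canal diameter (0.07–0.3 mm) to
CBCT voxel size. Canals near the apex are thinner than a 200 µm voxel and
a few voxels wide at 80 µm, exactly the regime in which resolution,
ground-truth fidelity and contrast interact. Absolute metric values from
clinical datasets are therefore not reproduced — orderings, monotonicities
and convergence properties are.

## Coordinate conventions

Arrays are `(z, y, x)` with axial slices at fixed `z`; voxel sizes are mm
per axis; the world coordinate of index `(k, j, i)` is
`origin + (k, j, i) · voxel_size` (voxel-center, 0-based). Crop boxes are
half-open index intervals. NIfTI files are written RAS+ with a diagonal
affine; arbitrary input NIfTIs are reoriented to this canonical frame on
read. Resampling maps an `n`-voxel axis at size `s` to `ceil(n·s/t)` voxels
at size `t` (world extent conserved to within one target voxel), sampling
at output voxel centers; out-of-support sites take the image minimum, so
background-padded crops behave like air around an isolated tooth.
Binarization sends ties at the threshold to foreground.

## Phantom generator

A tooth is the union of a crown ellipsoid (enamel shell over a dentin
core; the crown center sits just above the root junction so crown and
roots overlap in a solid neck) and 1–3 tapered root cones whose medial
axes may bend quadratically (lateral bend up to ~0.35 mm). The canal
system is a pulp-chamber ellipsoid inside the crown dentin joined to one
tapering tube per root (coronal radius 0.18–0.30 mm tapering to
0.07–0.12 mm) that ends 0.35 mm short of the apex, so the whole system is
an enclosed cavity — which is what thresholding a micro-CT of an intact
tooth resolves. Optional features: an accessory canal (a 0.4 × apical
radius lateral branch at a configurable root level) and, for molars, an
isthmus (a 0.1 mm web joining two canals mid-root, wrapped in a dentin
sheath so it stays internal where it crosses the furcation gap).

Intensities are enamel 2000 > dentin 1000 > canal = background 100
(arbitrary units) with Gaussian noise of sd 2% of the dentin mean. The
CBCT twin applies a rigid pose offset (rotation ≤ 10°, translation ≤ 1 mm
in cohorts), isotropic Gaussian blur (default σ = 1.0 × target voxel),
linear resampling to 200 or 80 µm, and additive noise (default sd 5% of a
dentin-level intensity). This reproduces, at image level, the
resolution-dependent canal–dentin contrast loss (separation in pooled-sd
units shrinks from ≈ 2.5 at 80 µm to ≈ 1.7 at 200 µm for a default
phantom). Not modeled: beam hardening, scatter, detector physics,
periodontal bone and neighboring teeth — so passing tests show the
pipeline's internal consistency and the stated mechanisms, not clinical
robustness to those confounds.

The manual-annotation surrogate dilates a label by `dilate_voxels`
(default 2 voxels ≈ 0.16 mm at 80 µm) and optionally toggles boundary
voxels at random (never below the 1-voxel eroded core). Dilation-only
degradation is a strict superset: recall of the original label is 1 while
precision falls — the over-inclusive-boundary behavior of manual CBCT
annotation. The comparison between label arms is directional only; no
quantitative model of annotator error is claimed.

## Ground-truth generation

Micro-CT thresholding uses Otsu's cut (or an explicit global value); the
tooth is the largest connected component, and the canal system is its
interior cavities — below-threshold voxels not reachable from the volume
border through background (6-connected flood fill). Surfaces are the
foreground voxels with a face-adjacent background neighbor, subsampled to
≤ 800 points. Registration is trimmed rigid ICP: nearest-neighbor
correspondences (KD-tree), the worst 10% of matches discarded, closed-form
SVD (Kabsch) alignment with determinant correction, centroid
initialization, stop at RMS improvement < 1e-4 mm or 100 iterations. The
trimmed RMS residual is provably non-increasing and is asserted as such.
The fixed surface comes from Otsu-thresholding the CBCT itself. Label
transfer pulls each target voxel center back through the inverse transform
and interpolates the mask as a 0/1 field, binarizing at 0.5 (nearest
available by flag); linear-then-threshold reduces aliasing relative to
nearest-neighbor transfer.

Note that a straight single-rooted phantom is nearly a solid of
revolution, so the azimuthal component of a pose is not identifiable from
its surface — ICP then returns a transform that aligns the surfaces
perfectly but differs from the generating pose by a rotation about the
tooth axis; label transfer is unaffected. Pose-recovery experiments
therefore use curved multi-rooted phantoms, which break the symmetry.

Ground-truth fidelity is measured by round-tripping a mask through a
coarser grid (identity pose) and back, reporting DSC against the original.
For tube-like canal masks this is non-increasing in voxel size — the
mechanism by which the ground truth itself degrades when high-resolution
models are registered to coarse CBCT grids, and the reason quantitative
metrics and visual quality can diverge across voxel sizes.

## Network and training

The segmentation network is a nested U: an outer encoder–decoder whose
stages are residual U-blocks (RSU). An RSU of height *h* applies an input
projection, an inner encoder with *h*−2 max-poolings, a dilated bottom
convolution, and an inner decoder with skip concatenations, adding the
projected input (residual). The deepest outer stages use a dilation-only
RSU (dilations 1-2-4) so receptive fields grow without further
downsampling. The bridge and every decoder stage emit a side logit map;
side maps are upsampled to full resolution and fused by a 1×1 convolution.
Training supervises the fused map and all side maps with mean binary
cross-entropy from logits (equal weights); an optional soft-Dice term on
the fused map (weight 0.5 by default for the canal stage) counters the
extreme foreground sparsity of thin canals.

Everything runs on 2D axial slices: the canonical architecture is 2D and
axial in-plane sizes are standardized by cropping; 3D convolution is an
extension point. Convolution blocks are conv → leaky ReLU (slope 0.01);
the leak keeps narrow-channel configurations trainable without batch
normalization. Weights use He-normal initialization, biases zero, all
seeded. The optimizer is Adam at learning rate 1e-3 (the full-scale
schedule is 400 epochs with the full six-stage network; every experiment
here uses the *tiny* preset — three outer stages, RSU height 3, ≈ 46k
parameters, input extents divisible by 4 — which is the configuration all
quantitative statements in this repository refer to). Augmentation: a
shared random in-plane rotation (±15°) and center crop-and-resize
(fraction 0.9–1.0) applied jointly to image and label per batch, labels
re-binarized at 0.5. Volumes are min–max normalized to [0, 1] before
slicing. The backward pass of every layer is hand-derived and checked
against central finite differences in the test suite.

Two-stage protocol: TS trains on (CBCT crop, tooth label); RCS trains on
the CBCT masked to the tooth-label region — outside voxels set to the
volume minimum, preserving grid alignment (rather than re-cropping to the
tooth bounding box) — against the canal label. At test time the cascade
uses the *predicted* tooth: TS output (binarized at 0.5, largest component
kept) gates the RCS input, and the canal prediction is intersected with
it, so canal ⊆ tooth by construction. The stages are trained
independently. When validation pairs are supplied, the best-validation
epoch's weights are kept; otherwise the final epoch's.

## Experiments and problem sizes

* **Overfit check**: one single-rooted phantom at 80 µm, 48² axial crops;
  TS 100 epochs, RCS 120 epochs (both within the 200-epoch budget);
  training DSC reaches ≥ 0.95 (tooth) and ≥ 0.9 (canal). This is the
  minimal evidence that architecture, label transfer and masking are wired
  consistently — not a generalization claim.
* **Label-arm comparison**: per seed, a fresh cohort of 8 single-rooted
  phantoms (6 train / 2 test) at 80 µm; one TS model per arm
  (micro-CT-guided vs 2-voxel-dilated labels), 12 epochs on 12 slices per
  tooth; both arms evaluated against micro-CT-guided test labels. The
  tooth stage carries the comparison because the dilation surrogate models
  over-estimated *tooth* boundaries. Expected ordering (micro-CT arm
  higher DSC and IOU, degraded arm SEN at least as high) holds in ≥ 4 of
  5 seeds; individual seeds can deviate when a short schedule underfits
  one arm.
* **Resampling study**: `run_resampling_experiment` regenerates labels on
  each resampled grid before retraining, so the ground truth varies with
  voxel size exactly as label transfer dictates; the fidelity curve above
  explains why metrics at different voxel sizes are not directly
  comparable.
* **Schedules** were sized for convergence of the tiny network on these
  phantom cohorts; they are desk-scale stand-ins for the full-scale
  profile (full network, 400 epochs), which is configured but not
  exercised by the tests.

## Degenerate inputs and numerical choices

Both-empty mask pairs score DSC = SEN = IOU = 1 by convention; an empty
ground truth against a non-empty prediction reports SEN = 0 with a flag.
Surface deviation is point-cloud-to-point-cloud between boundary voxel
centers (adequate at ≤ voxel-size scale; a mesh-based tool would
interpolate sub-voxel), signed by ground-truth membership of the predicted
point's voxel; the ±0.5 mm (tooth) and ±0.2 mm (canal) bands are reporting
windows only — no points are discarded. Empty masks raise for surface and
crop operations; an untrained or failed stage returns an empty mask with a
warning rather than raising, and an empty tooth stage yields an empty
canal mask. Connected components default to 26-connectivity; the
false-positive removal policies (`keep_largest_k`, `min_size`,
`keep_in_region` with a widest-axial-slice cervical surrogate) are
automatic, reproducible stand-ins for a visual screening step.

## Known limitations

The phantom is geometric, not anatomical: no C-shaped cross-sections
beyond an arc approximation, no enamel histology, no scanner artifacts.
The NumPy network is CPU-bound and desk-scale; the full-size preset exists
for structural fidelity, not for training at scale. Registration is
rigid-only (no scale estimation between scanner calibrations). The
manual-annotation surrogate captures the over-inclusion direction only.
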