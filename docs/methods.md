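# Methods

This note records the modelling choices behind `noduledet`, the parameters
that matter, what the synthetic phantoms do and do not emulate, and the
numerical conventions the tests rely on.

## Problem and model

Pulmonary-nodule detection in chest CT is a 3D object-detection problem with
extreme class imbalance: a few roughly-spherical targets of 3–90 mm against
~10⁷ voxels of parenchyma.  The package implements a one-stage dense
detector in the RetinaNet lineage: every anchor position on three feature
grids predicts an objectness probability and a 4-vector (centre offset,
log-diameter).  Because nodules are nearly spherical, anchors are cubes of
5, 10 and 20 voxels, and each ground truth is a (centre, diameter) sphere.

### Backbone variants

Three interchangeable backbones produce features at strides 2, 4, 8:

* `resnet` — pre-activation basic blocks (two 3³ convolutions);
* `resnext` — pre-activation bottlenecks whose 3³ convolution is grouped
  (cardinality `g`), with mid-width half the block width;
* `csp_resnext` — the cross-stage-partial variant: channels split 50/50,
  one half passes through a ResNeXt unit, halves are concatenated and fused
  by a 1×1×1 transition.  At equal width this removes roughly a quarter of
  the ResNeXt parameters (and ~3.7× fewer than the basic-block ResNet),
  which is the point of the design.

Pre-activation residual units (`x + conv(relu(norm(x)))`) were chosen so a
block with a zero-initialized final convolution is exactly the identity —
this makes the CSP wiring directly testable.  Normalization is GroupNorm:
desk-scale batches are one patch, so batch statistics are meaningless.
Convolution weights use He initialization; the classification head bias is
set so the initial foreground probability is ~1 % (the standard focal-loss
prior), without which the first epochs are spent collapsing the background.

The neck either passes per-level lateral projections straight to the heads
(`use_fpn=false`) or fuses them top-down with nearest-neighbour upsampling
and a 3³ smoothing convolution (`use_fpn=true`).  Heads are per-level (no
cross-level weight sharing): sharing saves little at these widths and the
engine's one-instance-per-call-site design stays simple.

Exact stage counts, widths and cardinality of the published full-scale
network are not recoverable from schematic figures; `ModelConfig` therefore
exposes them.  The desk default (`base_channels=8`, one block per stage,
cardinality 8 where width allows, width-limited otherwise) keeps a training
step ~0.3 s on one CPU.  `ModelConfig.full_scale()` is sized near the
~1.3 M-parameter regime of the original network but makes no claim of
architectural identity.

### Anchor assignment

`assign_iou` is classic fixed-threshold matching (positive ≥ 0.5, negative
< 0.3, low-quality matches forced positive so no ground truth is unmatched).
Its known failure mode — several positives per ground truth at stride/size
combinations that straddle the thresholds — is reproduced by a unit test.

`assign_nearest` implements the single-positive rule: per ground truth, the
anchor minimizing the lexicographic key

```
(squared distance of anchor point to centre, point z, point y, point x,
 |anchor size − diameter|, anchor size)
```

becomes positive.  The z/y/x terms break exact distance ties between
different points deterministically; the final size term breaks |size−d|
ties toward the smaller cube.  Anchors already claimed by an earlier ground
truth are skipped, so "exactly one positive per ground truth" holds even
for adjacent targets (processed in input order).  Non-positive anchors with
IoU > 0.3 against any ground truth are ignored — the ignored class is
named but not defined in the source material; penalizing near-hits as
negatives measurably destabilizes the tiny-sample regime, so this
threshold is our choice, config-exposed.

Anchor points sit at cell centres (`index·stride + stride/2`); regression
targets are `(gt_centre − point)/size` per axis and `ln(d/size)`, so
encode/decode are exact inverses.

## Loss and optimization

Classification: sigmoid focal loss, α = 0.25, γ = 2, summed over positive
and negative anchors and normalized by the positive count.  Regression:
smooth-L1 over positives, weight λ = 1.  Both gradients are closed-form.

The full-scale recipe follows the published one: Ranger — RAdam with
Lookahead (k = 6, α = 0.5) — with gradient centralization (per-filter mean
subtraction) on convolution weight gradients, constant learning rate 0.001,
200 epochs, and the three augmentations (xy flips, z-rotation 0–180°,
isotropic scale 0.75–1.25) applied identically to voxels and annotation
centres (diameters scale; rotations preserve a sphere's diameter).

The desk-scale harness (tests, acceptance script) instead selects the
plain-Adam option with batch size 1: its whole budget is ~720 optimizer
steps, and RAdam's variance warm-up plus the Lookahead pull-back consume
most of such a short schedule (measured: final loss 0.81 vs 0.38, held-out
sensitivity at 8 FP/scan 0.79–0.83 vs ≈ 1.0 under identical conditions).
This is a schedule-length adaptation, not a claim about the full recipe.

## Synthetic phantoms

A phantom is a soft-tissue body ellipsoid (≈ +40 HU) containing two lung
ellipsoids (≈ −850 HU) surrounded by air, with additive Gaussian noise
(σ = 25 HU) and values clipped to the normalization window [−1200, 600].
Nodules are spheres with:

* **diameter** from a log-normal law (median 9 mm, log-SD 0.45, truncated
  to [4, 40] mm and to fit the lungs) — right-skewed, as screening-cohort
  diameter distributions are;
* **solid fraction** from a three-band mixture over 0–10 % / 10–50 % /
  50–100 % (weights 0.3/0.4/0.3, uniform within band), the bands used when
  detection performance is stratified by consolidation.  The solid core is
  a centred inner sphere of volume = fraction × nodule volume at +40 HU,
  with a ground-glass rim at −600 HU — a one-parameter stand-in for the
  consolidation-to-tumor notion;
* placement strictly inside the lung mask (Euclidean distance transform
  margin) and pairwise non-overlapping, with bounded retries.

What the phantoms do **not** emulate: vessels and airways (the main FP
source in real CT), juxtapleural and spiculated morphology, scanner noise
texture, reconstruction-kernel effects, and anatomical lung shape.  A model
that passes the phantom suite has demonstrably correct plumbing, geometry
and optimization — not clinical performance.  The HU levels are
conventional textbook values, not fitted to any dataset.

## Inference and evaluation conventions

* Sliding window: 64³ patches, overlap 24 ≥ the largest anchor (20), so
  every nodule is fully interior to at least one tile; duplicate
  resolution is delegated entirely to one global greedy NMS at cube-IoU
  0.1 (nodules are sparse; a low threshold merges cross-tile duplicates).
* Candidate floor 0.05 before NMS, at most 100 detections per scan.
* Lung masking keeps detections whose rounded centre lies inside the mask
  dilated by 2 voxels.  `compute_lung_mask` thresholds at −320 HU, removes
  border-connected air, keeps the two largest interior components, closes,
  and fills holes (solid nodules are holes in an air mask).
* Hit criterion: detection centre within the ground-truth radius.  Each
  nodule is credited once (highest-probability hit); further hits are
  ignored, not false positives (config flag to change this).
* FROC thresholds sweep all distinct probabilities; sensitivities at the
  seven FP/scan rates are linearly interpolated (toward (0, 0) below the
  lowest achieved rate, clamped right of the highest); CPM is their
  arithmetic mean; folds aggregate as mean ± sample SD (ddof = 1).

## Numerical and engineering notes

* All tensors are float32, shaped `(C, D, H, W)` per sample; convolutions
  are im2col + BLAS matmul with explicit col2im backward.  Gradients of
  every layer are verified against central differences.
* Resampled sizes use round-half-away-from-zero (platform-stable);
  interpolation is trilinear for intensities, nearest for masks; voxel
  indices are 0-based voxel centres; world coordinates are (x, y, z) mm in
  the LUNA16 CSV dialect, arrays are (z, y, x).
* Determinism: every stage takes a seed; per-stage seeds derive from the
  global one via CRC32 tags (hash-randomization-proof); identical
  (inputs, config, seed) triples give identical detection lists.
* Degenerate inputs: empty ground-truth lists give all-negative
  assignments and a defined classification loss; volumes smaller than a
  patch are zero-padded; a missing lung mask degrades to pass-through with
  a warning; non-finite training loss aborts with a diagnostic.

## Problem sizes used by the test and acceptance harnesses

End-to-end runs train the reduced-width CSP-ResNeXt+FPN+nearest-anchor
detector on 24 patches of 64³ voxels from 6 phantoms (80×112×112 voxels,
3 nodules each) for 30 epochs, and score 8 held-out phantoms; the pruning
ladder runs all six configurations at a further reduced size (32³ patches,
2 epochs) to exercise structure and determinism rather than ranking
quality.  These sizes are the package's desk-scale presets; the full-scale
configuration is exposed but not exercised by the suite.

## Known limitations

* The engine is single-sample and CPU-bound; it is sized for method
  research, not throughput.
* The phantom's simplicity inflates absolute metrics; CPM values on
  phantoms are not comparable to values on clinical datasets.
* DICOM series ingestion, slice-thickness harmonization beyond isotropic
  resampling, and a second-stage false-positive-reduction classifier are
  out of scope.
* Oblique NIfTI affines are rejected rather than resliced.
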