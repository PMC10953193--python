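# noduledet

A 3D region proposal network (RPN) toolkit for pulmonary-nodule detection in
chest CT, built for method development at desk scale.  It implements the full
detection stack — preprocessing, a CSP-ResNeXt/FPN one-stage detector with
nearest-anchor training-sample selection, patch-based whole-volume inference
with lung masking, and FROC/CPM evaluation — and ships a synthetic-phantom
generator so the entire pipeline runs end-to-end on a single CPU without any
clinical data.

## Who this is for

Researchers working on lung-nodule computer-aided detection who need a
reference implementation of the one-stage 3D detection recipe (anchors of 5,
10 and 20 voxels over a three-level feature pyramid) and of the LUNA16-style
evaluation protocol, with every component testable against oracles on
synthetic data.

## The method

**Preprocessing.** CT volumes are resampled to 1 mm isotropic spacing
(trilinear) and intensities are mapped linearly from the HU window
[−1200, 600] to [0, 1] in single precision.

**Detector.** A backbone (ResNet, ResNeXt, or CSP-ResNeXt 3D blocks)
extracts features at strides 2, 4 and 8; an optional feature pyramid network
fuses them top-down; a dense head emits 15 channels per level — 3 anchor
sizes × (probability, z, y, x, d).  The CSP-ResNeXt block splits channels
50/50, routes one half through a grouped-convolution residual unit, and
fuses with a 1×1×1 transition, cutting parameters relative to plain ResNeXt
at equal width.

**Nearest-anchor assignment.** Fixed-IoU matching can hand several positive
anchors to one nodule.  The nearest-anchor rule instead makes exactly one
anchor positive per ground truth: the anchor whose point is closest
(Euclidean) to the nodule centre, with ties among sizes at one point broken
by the size closest to the nodule diameter.  Remaining anchors are negative,
except near-hits (IoU > 0.3), which are ignored by the loss.

**Loss and training.** Sigmoid focal loss (α = 0.25, γ = 2) over positive
and negative anchors plus smooth-L1 box regression over positives.  The
full-scale recipe is Ranger (RAdam + Lookahead with gradient centralization)
at a constant learning rate of 0.001 for 200 epochs, with random xy flips,
z-rotations in [0°, 180°], and isotropic scaling in [0.75, 1.25].

**Inference.** Overlapping 64³ patches tile the volume (overlap ≥ the
largest anchor), predictions are decoded to world coordinates, merged by
greedy 3D NMS, and detections outside a (dilated) lung mask are discarded.

**Evaluation.** A detection is a true positive when its centre lies within
the ground-truth radius.  The FROC curve sweeps all confidence thresholds;
sensitivity is read at 0.125, 0.25, 0.5, 1, 2, 4 and 8 false positives per
scan, and CPM is the mean of those seven values, with k-fold results
reported as mean ± SD.

The network runs on a compact, fully-tested numpy/BLAS layer engine
(`noduledet.nn`) with explicit forward/backward passes — no GPU or deep
learning framework is required at this scale.

## Worked example

```bash
noduledet simulate cohort/ --seed 1 --n-scans 4
noduledet train cohort/ run/ --seed 1
noduledet detect cohort/ run/model.ckpt.npz detections.csv
noduledet evaluate detections.csv cohort/annotations.csv metrics.csv
```

With the desk-scale preset (`noduledet.config.desk_config`), a run of the
complete pipeline — 6 training phantoms (24 patches of 64³ voxels, 30
epochs) and 8 held-out test phantoms — prints (seed 1):

```json
{
  "phantom_cpm_percent": {"value": 75.6, "n": 24},
  "phantom_sensitivity_at_2fp_percent": {"value": 70.8, "n": 24},
  "phantom_sensitivity_at_8fp_percent": {"value": 91.7, "n": 24},
  "final_training_loss": {"value": 0.3921, "n": 24}
}
```

meaning the detector recovers 70.8 % of the 24 held-out nodules at 2 false
positives per scan and 91.7 % at 8 per scan, for a competition performance
metric (mean sensitivity over the seven FP/scan operating points) of 75.6 %
on the synthetic cohort; exact values vary with the seed.  The
pruning-ladder harness (`noduledet prune-ladder`) repeats training across
the six backbone/neck/assignment configurations and emits one CPM per row.

## Layout

| Module | Role |
|---|---|
| `noduledet.volume` | MetaImage/NIfTI I/O, resampling, HU normalization, coordinates, patch sampling |
| `noduledet.phantom` | synthetic chest phantoms, annotations, cohorts |
| `noduledet.nn` | numpy layer engine and optimizers |
| `noduledet.model` | backbone / neck / head architectures |
| `noduledet.anchors` | anchor enumeration, IoU + nearest-anchor assignment, box coding |
| `noduledet.training` | loss, augmentation, training loop |
| `noduledet.inference` | sliding-window detection, NMS, lung masking |
| `noduledet.froc` | FROC curves, CPM, fold aggregation |
| `noduledet.pipeline` / `noduledet.cli` | reproducible stage runners and the CLI |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
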