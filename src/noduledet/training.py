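"""Loss, data augmentation and the detector training loop.

The loss is the RetinaNet-family combination: sigmoid focal loss over
positive and negative anchors (ignored anchors contribute nothing) plus
smooth-L1 on the box regression of positive anchors, both normalized by the
number of positives.  Training uses the Ranger optimizer (RAdam + Lookahead
with gradient centralization on convolution weights) at a constant learning
rate; a plain-Adam fallback is available.  Augmentation applies random xy
flips, a z-axis rotation in [0, 180] degrees and isotropic scaling in
[0.75, 1.25] to voxels and annotations alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .anchors import (AssignmentResult, GroundTruthBox, NEGATIVE, POSITIVE,
                      assign_iou, assign_nearest, enumerate_anchors)
from .model import HeadOutput, RPN3D, level_shapes
from .volume import Patch

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    optimizer: str = "ranger"            # "ranger" or "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 4
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    reg_weight: float = 1.0
    assignment: str = "nearest"          # "nearest" or "iou"
    grad_centralization: bool = True
    lookahead_k: int = 6
    lookahead_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("ranger", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.assignment not in ("nearest", "iou"):
            raise ValueError(f"unknown assignment {self.assignment!r}")


@dataclass
class AugmentConfig:
    flip_xy: bool = True
    rotate_z: tuple[float, float] = (0.0, 180.0)    # degrees
    scale: tuple[float, float] = (0.75, 1.25)

    def __post_init__(self) -> None:
        if self.scale[0] <= 0:
            raise ValueError("scale bounds must be positive")


@dataclass
class AugmentParams:
    flip_y: bool = False
    flip_x: bool = False
    angle_deg: float = 0.0
    scale: float = 1.0

    @property
    def is_identity(self) -> bool:
        return (not self.flip_y and not self.flip_x
                and self.angle_deg == 0.0 and self.scale == 1.0)


def draw_augment_params(rng: np.random.Generator, cfg: AugmentConfig) -> AugmentParams:
    return AugmentParams(
        flip_y=bool(cfg.flip_xy and rng.random() < 0.5),
        flip_x=bool(cfg.flip_xy and rng.random() < 0.5),
        angle_deg=float(rng.uniform(*cfg.rotate_z)),
        scale=float(rng.uniform(*cfg.scale)))


def _augment_matrix(params: AugmentParams) -> np.ndarray:
    """Forward spatial map in (z, y, x) coordinates about the patch centre."""
    th = math.radians(params.angle_deg)
    rot = np.array([[1, 0, 0],
                    [0, math.cos(th), -math.sin(th)],
                    [0, math.sin(th), math.cos(th)]])
    flip = np.diag([1.0, -1.0 if params.flip_y else 1.0,
                    -1.0 if params.flip_x else 1.0])
    return rot @ (params.scale * flip)


def apply_augmentation(
    patch: np.ndarray,
    nodules: Sequence[tuple[np.ndarray, float, float | None]],
    params: AugmentParams,
) -> tuple[np.ndarray, list[tuple[np.ndarray, float, float | None]]]:
    """Apply one spatial transform to voxels and patch-local annotations.

    Annotation centres follow the exact affine; diameters multiply by the
    scale factor (rotation and flips preserve a sphere's diameter).
    Annotations pushed outside the patch are dropped with a log entry.
    """
    if params.is_identity:
        return patch, list(nodules)
    m = _augment_matrix(params)
    center = (np.asarray(patch.shape, dtype=float) - 1.0) / 2.0
    m_inv = np.linalg.inv(m)
    out = ndimage.affine_transform(
        patch, m_inv, offset=center - m_inv @ center, order=1,
        mode="constant", cval=0.0)
    np.clip(out, 0.0, 1.0, out=out)
    new_nodules = []
    for c, diam, frac in nodules:
        c_new = m @ (np.asarray(c, dtype=float) - center) + center
        d_new = diam * params.scale
        if np.all(c_new >= 0) and np.all(c_new <= np.asarray(patch.shape) - 1):
            new_nodules.append((c_new, d_new, frac))
        else:
            log.info("augmentation moved a nodule outside the patch; dropped")
    return out.astype(np.float32), new_nodules


def augment(patch: np.ndarray, nodules, cfg: AugmentConfig, seed: int):
    """Draw a random transform (deterministic in `seed`) and apply it."""
    params = draw_augment_params(np.random.default_rng(seed), cfg)
    return apply_augmentation(patch, nodules, params)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

_EPS = 1e-7


def detection_loss(
    head_out: HeadOutput,
    assignment: AssignmentResult,
    focal_alpha: float = 0.25,
    focal_gamma: float = 2.0,
    reg_weight: float = 1.0,
    with_grads: bool = False,
):
    """Focal + smooth-L1 detection loss over assigned anchors.

    Returns ``(total, cls_term, reg_term)`` and, with ``with_grads``, the
    per-level gradients ``(d_cls, d_reg)`` ready for
    :meth:`RPN3D.backward_from_head`.  Ignored anchors contribute neither
    value nor gradient; the regression term covers positive anchors only.
    """
    logits, regs = head_out.flatten()
    labels = assignment.labels
    if len(labels) != len(logits):
        raise ValueError(
            f"assignment covers {len(labels)} anchors, head emits {len(logits)}")
    n_pos = max(assignment.n_positive, 1)
    a, g = focal_alpha, focal_gamma

    p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pos = labels == POSITIVE
    neg = labels == NEGATIVE
    cls_vals = np.zeros_like(p)
    cls_vals[pos] = -a * (1 - p[pos]) ** g * np.log(p[pos])
    cls_vals[neg] = -(1 - a) * p[neg] ** g * np.log(1 - p[neg])
    cls_term = float(cls_vals.sum()) / n_pos

    err = regs[pos].astype(np.float64) - assignment.targets[pos]
    abs_err = np.abs(err)
    reg_vals = np.where(abs_err < 1.0, 0.5 * err ** 2, abs_err - 0.5)
    reg_term = float(reg_vals.sum()) / n_pos
    total = cls_term + reg_weight * reg_term
    if not with_grads:
        return total, cls_term, reg_term

    dlogit = np.zeros_like(p)
    pp, pn = p[pos], p[neg]
    dlogit[pos] = a * (1 - pp) ** g * (g * pp * np.log(pp) - (1 - pp))
    dlogit[neg] = (1 - a) * pn ** g * (pn - g * (1 - pn) * np.log(1 - pn))
    dlogit /= n_pos
    dreg = np.zeros_like(regs, dtype=np.float64)
    dreg[pos] = reg_weight * np.clip(err, -1.0, 1.0) / n_pos

    # unflatten to per-level maps mirroring HeadOutput.flatten()
    d_cls, d_reg = [], []
    idx = 0
    for cl in head_out.cls_logits:
        a_ch, d, h, w = cl.shape
        n = a_ch * d * h * w
        d_cls.append(dlogit[idx:idx + n].reshape(d, h, w, a_ch)
                     .transpose(3, 0, 1, 2).astype(np.float32))
        d_reg.append(dreg[idx:idx + n].reshape(d, h, w, a_ch, 4)
                     .transpose(3, 4, 0, 1, 2).astype(np.float32))
        idx += n
    return total, cls_term, reg_term, (d_cls, d_reg)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: RPN3D
    history: list[dict] = field(default_factory=list)   # per-epoch loss terms


def _assign_fn(cfg: TrainConfig) -> Callable:
    return assign_nearest if cfg.assignment == "nearest" else assign_iou


def make_optimizer(model: RPN3D, cfg: TrainConfig):
    if cfg.optimizer == "ranger":
        return nn.make_ranger(model.params(), lr=cfg.learning_rate,
                              grad_centralization=cfg.grad_centralization,
                              lookahead_k=cfg.lookahead_k,
                              lookahead_alpha=cfg.lookahead_alpha)
    return nn.Adam(model.params(), lr=cfg.learning_rate,
                   grad_centralization=cfg.grad_centralization)


def train(
    model: RPN3D,
    patches: Sequence[Patch],
    train_cfg: TrainConfig,
    augment_cfg: AugmentConfig | None = None,
) -> TrainResult:
    """Train a detector on pre-sampled patches; fully seeded and CPU-only.

    Anchors are re-assigned every epoch (augmentation moves the ground
    truth); gradients accumulate over `batch_size` patches per optimizer
    step.  A NaN loss aborts with a diagnostic.
    """
    if not patches:
        raise ValueError("at least one training patch is required")
    shape = patches[0].voxels.shape
    grid = enumerate_anchors(level_shapes(shape, model.cfg.pyramid_strides),
                             model.cfg.pyramid_strides, model.cfg.anchor_sizes)
    assign = _assign_fn(train_cfg)
    opt = make_optimizer(model, train_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    history: list[dict] = []

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(patches))
        tot = cls = reg = 0.0
        in_batch = 0
        model.zero_grad()
        for i in order:
            patch = patches[i]
            voxels, nodules = patch.voxels, patch.nodules
            if augment_cfg is not None:
                params = draw_augment_params(rng, augment_cfg)
                voxels, nodules = apply_augmentation(voxels, nodules, params)
            gts = [GroundTruthBox(tuple(c), float(d)) for c, d, _ in nodules]
            assignment = assign(grid, gts)
            out = model.forward(voxels)
            t, c, r, (d_cls, d_reg) = detection_loss(
                out, assignment, train_cfg.focal_alpha, train_cfg.focal_gamma,
                train_cfg.reg_weight, with_grads=True)
            if not np.isfinite(t):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"patch {i} (cls={c}, reg={r})")
            model.backward_from_head(d_cls, d_reg)
            tot += t
            cls += c
            reg += r
            in_batch += 1
            if in_batch == train_cfg.batch_size:
                for p in model.params():
                    p.grad /= in_batch
                opt.step()
                model.zero_grad()
                in_batch = 0
        if in_batch:
            for p in model.params():
                p.grad /= in_batch
            opt.step()
            model.zero_grad()
        n = len(patches)
        history.append({"epoch": epoch, "loss": tot / n,
                        "cls_loss": cls / n, "reg_loss": reg / n})
        log.info("epoch=%d loss=%.5f cls=%.5f reg=%.5f",
                 epoch, tot / n, cls / n, reg / n)
    return TrainResult(model=model, history=history)
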