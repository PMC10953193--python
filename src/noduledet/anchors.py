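"""Anchor enumeration, positive/negative assignment and box coding.

Anchors are cubes of 5, 10 or 20 voxels attached to feature-grid points.
Anchor points sit at cell centres: ``point = grid_index * stride + stride/2``.
Two assignment strategies are provided:

* ``assign_iou`` — classic fixed-IoU matching (RetinaNet lineage), which can
  hand several positive anchors to one ground truth;
* ``assign_nearest`` — the nearest-anchor rule: for each ground truth,
  exactly one anchor becomes positive, namely the one whose anchor point is
  closest (Euclidean) to the ground-truth centre, with ties among anchors
  sharing that point broken by the size closest to the ground-truth
  diameter.

Regression targets parameterize the offset from anchor point to box centre
in units of the anchor size, and the diameter as a log ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

ANCHOR_SIZES = (5.0, 10.0, 20.0)

POSITIVE, NEGATIVE, IGNORE = 1, 0, -1


@dataclass
class AnchorGrid:
    """Flat arrays describing every anchor, in deterministic order.

    Ordering is level-major, then z, y, x grid index, then size ascending —
    exactly the layout in which the dense head emits its channels.
    """

    points: np.ndarray   # (N, 3) float, (z, y, x) input-voxel coordinates
    sizes: np.ndarray    # (N,) float
    levels: np.ndarray   # (N,) int

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass
class GroundTruthBox:
    center: tuple[float, float, float]   # (z, y, x) voxels
    diameter: float                      # voxels

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclass
class AssignmentResult:
    labels: np.ndarray       # (N,) int8: POSITIVE / NEGATIVE / IGNORE
    matched_gt: np.ndarray   # (N,) int32, gt index for positives, else -1
    targets: np.ndarray      # (N, 4) float32: (dz, dy, dx, dd) for positives

    @property
    def n_positive(self) -> int:
        return int((self.labels == POSITIVE).sum())


def enumerate_anchors(
    level_shapes: Sequence[tuple[int, int, int]],
    strides: Sequence[int],
    sizes: Sequence[float] = ANCHOR_SIZES,
) -> AnchorGrid:
    """Enumerate one anchor per (level, grid cell, size)."""
    pts, szs, lvls = [], [], []
    n_sizes = len(sizes)
    sizes_arr = np.asarray(sizes, dtype=np.float64)
    for lvl, (shape, stride) in enumerate(zip(level_shapes, strides)):
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        grid = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(np.float64)
        cell_pts = grid * stride + stride / 2.0
        pts.append(np.repeat(cell_pts, n_sizes, axis=0))
        szs.append(np.tile(sizes_arr, len(cell_pts)))
        lvls.append(np.full(len(cell_pts) * n_sizes, lvl, dtype=np.int32))
    return AnchorGrid(points=np.concatenate(pts), sizes=np.concatenate(szs),
                      levels=np.concatenate(lvls))


def iou_cube(center_a: Sequence[float], size_a: float,
             center_b: Sequence[float], size_b: float) -> float:
    """Intersection-over-union of two axis-aligned cubes."""
    a = np.asarray(center_a, dtype=float)
    b = np.asarray(center_b, dtype=float)
    lo = np.maximum(a - size_a / 2.0, b - size_b / 2.0)
    hi = np.minimum(a + size_a / 2.0, b + size_b / 2.0)
    edge = np.clip(hi - lo, 0.0, None)
    inter = float(np.prod(edge))
    union = size_a ** 3 + size_b ** 3 - inter
    return inter / union if union > 0 else 0.0


def _iou_matrix(anchors: AnchorGrid, gts: Sequence[GroundTruthBox]) -> np.ndarray:
    """(N_anchors, N_gts) cube IoU, vectorized over anchors."""
    n, m = len(anchors), len(gts)
    out = np.zeros((n, m), dtype=np.float64)
    half_a = anchors.sizes[:, None] / 2.0
    for j, gt in enumerate(gts):
        c = np.asarray(gt.center, dtype=float)
        r = gt.diameter / 2.0
        lo = np.maximum(anchors.points - half_a, c - r)
        hi = np.minimum(anchors.points + half_a, c + r)
        inter = np.prod(np.clip(hi - lo, 0.0, None), axis=1)
        union = anchors.sizes ** 3 + gt.diameter ** 3 - inter
        out[:, j] = inter / union
    return out


def encode_targets(point: np.ndarray, size: float, gt: GroundTruthBox) -> np.ndarray:
    """(dz, dy, dx, dd): centre offset in anchor-size units, log size ratio."""
    if gt.diameter <= 0:
        raise ValueError("diameter must be positive")
    offsets = (np.asarray(gt.center, dtype=float) - np.asarray(point)) / size
    return np.append(offsets, np.log(gt.diameter / size)).astype(np.float32)


def decode_prediction(point: np.ndarray, size: float,
                      regression: Sequence[float]) -> tuple[np.ndarray, float]:
    """Invert :func:`encode_targets`: returns (centre (z,y,x), diameter)."""
    reg = np.asarray(regression, dtype=float)
    center = np.asarray(point, dtype=float) + reg[:3] * size
    return center, float(size * np.exp(reg[3]))


def assign_iou(anchors: AnchorGrid, gts: Sequence[GroundTruthBox],
               pos_threshold: float = 0.5, neg_threshold: float = 0.3) -> AssignmentResult:
    """Fixed-IoU matching with low-quality-match forcing.

    Positive where max IoU >= `pos_threshold`, negative where < `neg_threshold`,
    ignore between; a ground truth left without a positive claims its
    highest-IoU anchor.
    """
    if pos_threshold < neg_threshold:
        raise ValueError("pos_threshold must be >= neg_threshold")
    n = len(anchors)
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int32)
    targets = np.zeros((n, 4), dtype=np.float32)
    if gts:
        iou = _iou_matrix(anchors, gts)
        best = iou.max(axis=1)
        arg = iou.argmax(axis=1)
        labels[(best >= neg_threshold) & (best < pos_threshold)] = IGNORE
        pos = best >= pos_threshold
        labels[pos] = POSITIVE
        matched[pos] = arg[pos]
        for j in range(len(gts)):
            if not np.any(pos & (arg == j)):
                k = int(iou[:, j].argmax())
                labels[k] = POSITIVE
                matched[k] = j
        for k in np.nonzero(labels == POSITIVE)[0]:
            targets[k] = encode_targets(anchors.points[k], anchors.sizes[k],
                                        gts[matched[k]])
    return AssignmentResult(labels, matched, targets)


def assign_nearest(anchors: AnchorGrid, gts: Sequence[GroundTruthBox],
                   ignore_iou: float = 0.3) -> AssignmentResult:
    """Nearest-anchor assignment: exactly one positive anchor per ground truth.

    For each ground truth (in input order) the available anchor minimizing
    ``(distance to centre, point z, point y, point x, |size - diameter|,
    size)`` lexicographically becomes positive; remaining anchors are
    negative except near-hits (IoU > `ignore_iou` with any ground truth),
    which are ignored and excluded from the loss.
    """
    n = len(anchors)
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int32)
    targets = np.zeros((n, 4), dtype=np.float32)
    if not gts:
        return AssignmentResult(labels, matched, targets)

    iou = _iou_matrix(anchors, gts)
    labels[iou.max(axis=1) > ignore_iou] = IGNORE

    taken: set[int] = set()
    for j, gt in enumerate(gts):
        c = np.asarray(gt.center, dtype=float)
        d2 = ((anchors.points - c) ** 2).sum(axis=1)
        size_gap = np.abs(anchors.sizes - gt.diameter)
        order = np.lexsort((anchors.sizes, size_gap,
                            anchors.points[:, 2], anchors.points[:, 1],
                            anchors.points[:, 0], d2))
        for k in order:
            if int(k) not in taken:
                break
        k = int(k)
        taken.add(k)
        labels[k] = POSITIVE
        matched[k] = j
        targets[k] = encode_targets(anchors.points[k], anchors.sizes[k], gt)
    return AssignmentResult(labels, matched, targets)


def dump_assignment_csv(anchors: AnchorGrid, result: AssignmentResult,
                        path) -> None:
    """Debug dump: one CSV row per anchor with its label and match."""
    import pandas as pd

    pd.DataFrame({
        "level": anchors.levels,
        "point_z": anchors.points[:, 0],
        "point_y": anchors.points[:, 1],
        "point_x": anchors.points[:, 2],
        "size": anchors.sizes,
        "label": result.labels,
        "matched_gt": result.matched_gt,
    }).to_csv(path, index=False)
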