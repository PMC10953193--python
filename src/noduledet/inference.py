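"""Whole-volume detection: sliding-window inference, NMS, lung masking.

A normalized volume is tiled with overlapping patches (overlap at least the
largest anchor so no nodule is split undetectably); per-patch predictions
are decoded to volume voxel and then world coordinates; duplicates across
tiles are resolved by one global greedy NMS; finally detections whose
centre falls outside a (dilated) lung mask are discarded, removing
extrapulmonary false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .anchors import enumerate_anchors, iou_cube
from .model import RPN3D, level_shapes
from .volume import CTVolume, NormalizedVolume, voxel_to_world

log = logging.getLogger(__name__)


@dataclass
class Detection:
    scan_id: str
    center_world: tuple[float, float, float]   # (x, y, z) mm
    center_voxel: tuple[float, float, float]   # (z, y, x)
    diameter: float                            # mm
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclass
class InferenceConfig:
    patch_size: int = 64
    patch_overlap: int = 24
    probability_floor: float = 0.05
    nms_iou: float = 0.1
    max_detections_per_scan: int = 100

    def __post_init__(self) -> None:
        if self.patch_overlap < 20:
            raise ValueError(
                "patch_overlap must be >= 20 voxels (the largest anchor)")
        if self.patch_overlap >= self.patch_size:
            raise ValueError("patch_overlap must be below patch_size")


def _tile_starts(extent: int, patch: int, overlap: int) -> list[int]:
    if extent <= patch:
        return [0]
    step = patch - overlap
    starts = list(range(0, extent - patch, step))
    starts.append(extent - patch)
    return sorted(set(starts))


def sliding_window_detect(
    vol: NormalizedVolume,
    model: RPN3D,
    cfg: InferenceConfig,
) -> list[Detection]:
    """Detect nodules across a whole normalized volume.

    Volumes smaller than a patch are zero-padded.  The returned list is
    NMS-resolved, capped at `max_detections_per_scan`, and sorted by
    descending probability.
    """
    size = cfg.patch_size
    shape = vol.shape
    grid = enumerate_anchors(level_shapes((size,) * 3, model.cfg.pyramid_strides),
                             model.cfg.pyramid_strides, model.cfg.anchor_sizes)
    raw: list[Detection] = []
    spacing = float(np.mean(vol.spacing))
    starts = [_tile_starts(s, size, cfg.patch_overlap) for s in shape]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                tile = np.zeros((size, size, size), dtype=np.float32)
                sub = vol.voxels[z0:z0 + size, y0:y0 + size, x0:x0 + size]
                tile[:sub.shape[0], :sub.shape[1], :sub.shape[2]] = sub
                logits, regs = model.forward(tile).flatten()
                probs = 1.0 / (1.0 + np.exp(-logits))
                keep = np.nonzero(probs >= cfg.probability_floor)[0]
                for k in keep:
                    center = grid.points[k] + regs[k, :3] * grid.sizes[k]
                    diam = float(grid.sizes[k] * np.exp(regs[k, 3]))
                    cv = center + np.array([z0, y0, x0], dtype=float)
                    raw.append(Detection(
                        scan_id=vol.scan_id,
                        center_world=tuple(float(v) for v in voxel_to_world(cv, vol)),
                        center_voxel=tuple(float(v) for v in cv),
                        diameter=diam * spacing,
                        probability=float(probs[k])))
    kept = nms_3d(raw, cfg.nms_iou)
    return kept[:cfg.max_detections_per_scan]


def nms_3d(dets: Sequence[Detection], nms_iou: float) -> list[Detection]:
    """Greedy non-maximum suppression on cube IoU (cube side = diameter).

    Detections are visited by descending probability (stable in input order
    on ties); one is suppressed if its IoU with any kept detection exceeds
    `nms_iou`.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].probability)
    kept: list[Detection] = []
    for i in order:
        d = dets[i]
        if all(iou_cube(d.center_voxel, d.diameter, k.center_voxel, k.diameter)
               <= nms_iou for k in kept):
            kept.append(d)
    return kept


def mask_filter(dets: Sequence[Detection], lung_mask: np.ndarray | None,
                margin: int = 2) -> list[Detection]:
    """Keep detections whose rounded centre lies in the dilated lung mask."""
    if lung_mask is None:
        log.warning("no lung mask supplied; mask filtering skipped")
        return list(dets)
    mask = lung_mask.astype(bool)
    if margin > 0:
        mask = ndimage.binary_dilation(mask, iterations=margin)
    out = []
    for d in dets:
        v = np.round(d.center_voxel).astype(int)
        if np.all(v >= 0) and np.all(v < mask.shape) and mask[tuple(v)]:
            out.append(d)
    return out


def compute_lung_mask(vol: CTVolume, threshold_hu: float = -320.0) -> np.ndarray:
    """Segment the lungs: threshold, drop border-connected air, keep the two
    largest interior components, then morphological closing."""
    air = vol.voxels < threshold_hu
    labels, n = ndimage.label(air)
    if n == 0:
        log.warning("scan %s: no sub-threshold voxels; empty lung mask",
                    vol.scan_id)
        return np.zeros(vol.shape, dtype=bool)
    border = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[border] = 0
    interior = np.nonzero(counts)[0]
    if interior.size == 0:
        log.warning("scan %s: no interior air component; empty lung mask",
                    vol.scan_id)
        return np.zeros(vol.shape, dtype=bool)
    keep = interior[np.argsort(counts[interior])[::-1][:2]]
    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)), iterations=2)
    # solid nodules are holes in the air mask; fill them back in
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Detections CSV (LUNA16 submission dialect + diameter column)
# ---------------------------------------------------------------------------

_DET_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "probability",
                "diameter_mm"]


def write_detections(dets: Sequence[Detection], path: str | Path) -> None:
    pd.DataFrame([[d.scan_id, d.center_world[0], d.center_world[1],
                   d.center_world[2], d.probability, d.diameter]
                  for d in dets], columns=_DET_COLUMNS).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detections CSV.

    ``center_voxel`` is filled with the world coordinate reordered to
    (z, y, x); it is exact on the 1 mm / zero-origin grid the pipeline
    writes and is not used by the FROC evaluation (which matches in world
    millimetres).
    """
    df = pd.read_csv(path)
    return [Detection(
        scan_id=str(r.seriesuid),
        center_world=(float(r.coordX), float(r.coordY), float(r.coordZ)),
        center_voxel=(float(r.coordZ), float(r.coordY), float(r.coordX)),
        diameter=float(getattr(r, "diameter_mm", 5.0)),
        probability=float(r.probability)) for r in df.itertuples(index=False)]
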