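"""CT volume I/O, isotropic resampling, HU normalization and patch sampling.

Conventions
-----------
* Voxel arrays are ordered ``(z, y, x)``; ``spacing`` and the stored
  ``origin`` follow the same ``(z, y, x)`` order.
* World coordinates at the interfaces (annotation CSVs, ``world_to_voxel``
  / ``voxel_to_world``) are ``(x, y, z)`` millimetres, matching the LUNA16
  annotation dialect.
* Voxel indices are 0-based and refer to voxel centres:
  ``world(v) = origin + v * spacing`` per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for unreadable or non-conforming image files."""


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units with world geometry."""

    voxels: np.ndarray          # (z, y, x), HU
    spacing: tuple[float, float, float]   # mm per axis, (z, y, x)
    origin: tuple[float, float, float]    # world mm of voxel (0,0,0), (z, y, x)
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must have 3 axes, got {self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NormalizedVolume:
    """Volume with intensities linearly mapped to [0, 1], single precision."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    scan_id: str = ""

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NoduleAnnotation:
    """One ground-truth nodule in world coordinates."""

    scan_id: str
    center_world: tuple[float, float, float]   # (x, y, z) mm
    diameter: float                            # mm
    solid_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")


@dataclass
class PreprocessConfig:
    hu_min: float = -1200.0
    hu_max: float = 600.0
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patch_size: int = 64
    patches_per_scan: int = 4
    positive_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.hu_min >= self.hu_max:
            raise ValueError("hu_min must be below hu_max")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing components must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> CTVolume:
    """Read a MetaImage (.mhd/.mha) or NIfTI (.nii/.nii.gz) volume.

    Axes are returned in ``(z, y, x)`` order with spacing and origin
    converted to the same convention.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected 3D image, got {img.GetDimension()}D")
        voxels = sitk.GetArrayFromImage(img)          # already (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))   # sitk reports (x, y, z)
        origin = tuple(reversed(img.GetOrigin()))
    elif name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 3D image, got {data.ndim}D")
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
            raise FormatError(f"{path}: oblique NIfTI affines are not supported")
        zooms = np.abs(np.diag(affine[:3, :3]))
        if np.any(zooms <= 0):
            raise FormatError(f"{path}: missing or degenerate voxel spacing")
        voxels = np.ascontiguousarray(data.transpose(2, 1, 0))   # (x,y,z) -> (z,y,x)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = tuple(float(v) for v in affine[:3, 3][::-1])
    else:
        raise FormatError(f"unsupported volume format: {path}")
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, scan_id=path.stem)


def write_volume(vol: CTVolume | NormalizedVolume, path: str | Path) -> None:
    """Write a volume as MetaImage or NIfTI, preserving spacing and origin."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        img = sitk.GetImageFromArray(np.asarray(vol.voxels))
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, str(path))
    elif name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing[::-1]
        affine[:3, 3] = vol.origin[::-1]
        nib.save(nib.Nifti1Image(np.asarray(vol.voxels).transpose(2, 1, 0), affine),
                 str(path))
    else:
        raise FormatError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_isotropic(vol: CTVolume, cfg: PreprocessConfig) -> CTVolume:
    """Trilinearly resample a volume to the configured target spacing.

    The output size per axis is ``round(size * spacing / target)`` with
    round-half-away-from-zero; the world origin is preserved (voxel centres
    stay anchored at ``origin``).
    """
    if any(s < 2 for s in vol.shape):
        raise ValueError(f"degenerate axis in volume shape {vol.shape}")
    target = np.asarray(cfg.target_spacing, dtype=float)
    spacing = np.asarray(vol.spacing, dtype=float)
    in_shape = np.asarray(vol.shape)
    out_shape = _round_half_away(in_shape * spacing / target).astype(int)
    if np.array_equal(out_shape, in_shape) and np.allclose(spacing, target):
        return CTVolume(vol.voxels.copy(), tuple(target), vol.origin, vol.scan_id)
    scale = target / spacing   # output index -> input index
    out = ndimage.affine_transform(
        vol.voxels.astype(np.float32), np.diag(scale), offset=0.0,
        output_shape=tuple(out_shape), order=1, mode="nearest")
    return CTVolume(out, tuple(target), vol.origin, vol.scan_id)


def normalize_hu(vol: CTVolume, cfg: PreprocessConfig) -> NormalizedVolume:
    """Map HU linearly onto [0, 1] with clipping outside the window."""
    scaled = (vol.voxels.astype(np.float32) - cfg.hu_min) / (cfg.hu_max - cfg.hu_min)
    return NormalizedVolume(np.clip(scaled, 0.0, 1.0).astype(np.float32),
                            vol.spacing, vol.origin, vol.scan_id)


def preprocess(vol: CTVolume, cfg: PreprocessConfig) -> NormalizedVolume:
    """Resample to isotropic target spacing, then normalize intensities."""
    return normalize_hu(resample_isotropic(vol, cfg), cfg)


def world_to_voxel(p: Sequence[float], vol: CTVolume | NormalizedVolume) -> np.ndarray:
    """Convert a world point (x, y, z) mm to a continuous (z, y, x) voxel index."""
    p_zyx = np.asarray(p, dtype=float)[::-1]
    return (p_zyx - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def voxel_to_world(v: Sequence[float], vol: CTVolume | NormalizedVolume) -> np.ndarray:
    """Convert a continuous (z, y, x) voxel index to a world point (x, y, z) mm."""
    v = np.asarray(v, dtype=float)
    return (np.asarray(vol.origin) + v * np.asarray(vol.spacing))[::-1]


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A training patch with annotations in patch-local voxel coordinates."""

    voxels: np.ndarray                 # (p, p, p) in [0, 1]
    origin_voxel: tuple[int, int, int]  # patch origin in the source volume grid
    scan_id: str = ""
    # (center_zyx voxels, diameter voxels, solid_fraction) per contained nodule
    nodules: list[tuple[np.ndarray, float, float | None]] = field(default_factory=list)


def _extract_patch(voxels: np.ndarray, origin: np.ndarray, size: int) -> np.ndarray:
    """Extract a cubic patch, zero-padding where it leaves the volume."""
    out = np.zeros((size, size, size), dtype=np.float32)
    lo = np.maximum(origin, 0)
    hi = np.minimum(origin + size, voxels.shape)
    if np.any(lo >= hi):
        return out
    dst_lo = lo - origin
    dst_hi = dst_lo + (hi - lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = (
        voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
    return out


def sample_training_patches(
    vol: NormalizedVolume,
    anns: Sequence[NoduleAnnotation],
    cfg: PreprocessConfig,
    seed: int,
    lung_mask: np.ndarray | None = None,
) -> list[Patch]:
    """Draw a deterministic mix of positive and negative training patches.

    Positive patches are centred on a nodule with uniform jitter up to a
    quarter patch; negative patches are drawn uniformly inside the lung-mask
    bounding box (whole volume when no mask is given) and re-drawn a bounded
    number of times if they happen to contain a nodule centre.
    """
    rng = np.random.default_rng(seed)
    size = cfg.patch_size
    n_total = cfg.patches_per_scan
    n_pos = int(round(n_total * cfg.positive_fraction))
    if anns and n_pos == 0 and cfg.positive_fraction > 0:
        n_pos = 1
    if not anns and cfg.positive_fraction > 0:
        log.warning("scan %s: no annotations; emitting only negative patches",
                    vol.scan_id)
        n_pos = 0
    centers_voxel = [world_to_voxel(a.center_world, vol) for a in anns]
    spacing = float(np.mean(vol.spacing))

    if lung_mask is not None and lung_mask.any():
        nz = np.nonzero(lung_mask)
        bbox_lo = np.array([int(a.min()) for a in nz])
        bbox_hi = np.array([int(a.max()) + 1 for a in nz])
    else:
        bbox_lo = np.zeros(3, dtype=int)
        bbox_hi = np.asarray(vol.shape)

    def local_annotations(origin: np.ndarray) -> list[tuple[np.ndarray, float, float | None]]:
        out = []
        for ann, cv in zip(anns, centers_voxel):
            local = cv - origin
            if np.all(local >= 0) and np.all(local < size):
                out.append((local, ann.diameter / spacing, ann.solid_fraction))
        return out

    patches: list[Patch] = []
    for i in range(n_pos):
        cv = centers_voxel[i % len(anns)]
        jitter = rng.integers(-(size // 4), size // 4 + 1, size=3)
        origin = np.round(cv).astype(int) - size // 2 + jitter
        origin = np.clip(origin, -size // 4,
                         np.maximum(np.asarray(vol.shape) - size + size // 4, 0))
        patches.append(Patch(_extract_patch(vol.voxels, origin, size),
                             tuple(int(o) for o in origin), vol.scan_id,
                             local_annotations(origin)))
    for _ in range(n_total - n_pos):
        for _attempt in range(20):
            hi = np.maximum(bbox_hi - size, bbox_lo + 1)
            origin = rng.integers(bbox_lo, hi, size=3)
            if not local_annotations(origin) or not anns:
                break
        patches.append(Patch(_extract_patch(vol.voxels, origin, size),
                             tuple(int(o) for o in origin), vol.scan_id,
                             local_annotations(origin)))
    return patches
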