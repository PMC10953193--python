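"""Synthetic chest-CT phantoms with spherical lung nodules.

A phantom is a body ellipsoid of soft tissue containing two lung ellipsoids
of air-like parenchyma; nodules are spheres whose solid core (soft-tissue HU)
occupies a controlled fraction of the sphere volume, surrounded by a
ground-glass rim.  Nodule diameters follow a truncated log-normal law
(right-skewed, as screening-cohort diameter distributions are) and the
solid-component fraction is drawn from a three-band mixture
(0-10%, 10-50%, 50-100%), mirroring how detection performance is commonly
stratified by consolidation.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, NoduleAnnotation, voxel_to_world, write_volume

log = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Raised when the requested nodules cannot be placed without overlap."""


@dataclass
class PhantomConfig:
    volume_shape: tuple[int, int, int] = (80, 112, 112)   # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)   # world mm, (z, y, x)
    n_nodules: int = 3
    diameter_median: float = 9.0        # mm, log-normal median
    diameter_sigma: float = 0.45        # log-space sd
    diameter_range: tuple[float, float] = (4.0, 40.0)
    solid_fraction_weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    hu_air: float = -1000.0
    hu_lung: float = -850.0
    hu_body: float = 40.0
    hu_solid: float = 40.0
    hu_ggo: float = -600.0
    noise_sd: float = 25.0              # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be non-negative")
        if abs(sum(self.solid_fraction_weights) - 1.0) > 1e-9:
            raise ValueError("solid_fraction_weights must sum to 1")
        if self.diameter_range[0] >= min(self.volume_shape):
            raise ValueError("diameter bounds exceed volume extent")


_SOLID_BANDS = ((0.0, 0.10), (0.10, 0.50), (0.50, 1.0))


@dataclass
class Phantom:
    volume: CTVolume
    lung_mask: np.ndarray
    annotations: list[NoduleAnnotation] = field(default_factory=list)


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray,
                    radii: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return (((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2) <= 1.0


def _sample_diameter(rng: np.random.Generator, cfg: PhantomConfig) -> float:
    lo, hi = cfg.diameter_range
    hi = min(hi, 0.4 * min(cfg.volume_shape) * min(cfg.spacing))
    for _ in range(1000):
        d = float(np.exp(rng.normal(np.log(cfg.diameter_median), cfg.diameter_sigma)))
        if lo <= d <= hi:
            return d
    return lo


def _sample_solid_fraction(rng: np.random.Generator, cfg: PhantomConfig) -> float:
    band = rng.choice(3, p=cfg.solid_fraction_weights)
    lo, hi = _SOLID_BANDS[band]
    return float(rng.uniform(lo, hi))


def generate_phantom(cfg: PhantomConfig) -> Phantom:
    """Generate one phantom: body + two lungs + non-overlapping nodule spheres."""
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.volume_shape
    spacing = np.asarray(cfg.spacing)
    hu = np.full(shape, cfg.hu_air, dtype=np.float32)

    center = np.asarray(shape) / 2.0
    body_radii = np.asarray(shape) * np.array([0.48, 0.44, 0.46])
    body = _ellipsoid_mask(shape, center, body_radii)
    hu[body] = cfg.hu_body

    lung_radii = np.asarray(shape) * np.array([0.37, 0.31, 0.19])
    offset_x = shape[2] * 0.22
    left = _ellipsoid_mask(shape, center - np.array([0, 0, offset_x]), lung_radii)
    right = _ellipsoid_mask(shape, center + np.array([0, 0, offset_x]), lung_radii)
    # clip to an eroded body so a soft-tissue shell always encloses the lungs
    lung_mask = (left | right) & ndimage.binary_erosion(body, iterations=2)
    hu[lung_mask] = cfg.hu_lung

    # distance (in voxels) to the lung-mask boundary, for safe sphere placement
    edt = ndimage.distance_transform_edt(lung_mask)
    annotations: list[NoduleAnnotation] = []
    placed: list[tuple[np.ndarray, float]] = []    # (center voxel, radius voxels)
    vol = CTVolume(hu, tuple(cfg.spacing), tuple(cfg.origin),
                   scan_id=f"phantom-{cfg.seed:06d}")

    cand_cache: dict[int, np.ndarray] = {}
    for i in range(cfg.n_nodules):
        for _attempt in range(200):
            d_mm = _sample_diameter(rng, cfg)
            r_vox = d_mm / (2.0 * float(np.mean(spacing)))
            key = int(np.ceil(r_vox + 1.0))
            if key not in cand_cache:
                cand_cache[key] = np.argwhere(edt > key)
            candidates = cand_cache[key]
            if candidates.size == 0:
                continue
            c = candidates[rng.integers(len(candidates))].astype(float)
            if all(np.linalg.norm(c - pc) > r_vox + pr + 2.0 for pc, pr in placed):
                break
        else:
            raise PlacementError(
                f"could not place nodule {i + 1}/{cfg.n_nodules} without overlap")
        frac = _sample_solid_fraction(rng, cfg)
        zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
        dist2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        sphere = dist2 <= r_vox ** 2
        # solid core: centred inner sphere holding `frac` of the nodule volume
        core = dist2 <= (r_vox * frac ** (1.0 / 3.0)) ** 2
        hu[sphere] = cfg.hu_ggo
        hu[core & sphere] = cfg.hu_solid
        placed.append((c, r_vox))
        annotations.append(NoduleAnnotation(
            scan_id=vol.scan_id,
            center_world=tuple(float(v) for v in voxel_to_world(c, vol)),
            diameter=d_mm, solid_fraction=frac))

    if cfg.noise_sd > 0:
        hu += rng.normal(0.0, cfg.noise_sd, size=shape).astype(np.float32)
    np.clip(hu, -1200.0, 600.0, out=hu)
    return Phantom(volume=vol, lung_mask=lung_mask, annotations=annotations)


def generate_cohort(cfg: PhantomConfig, n_scans: int, seed: int) -> list[Phantom]:
    """Generate independent phantoms with per-scan seeds derived from `seed`."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    scan_seeds = rng.integers(0, 2 ** 31 - 1, size=n_scans)
    return [generate_phantom(replace(cfg, seed=int(s))) for s in scan_seeds]


# ---------------------------------------------------------------------------
# Annotation CSV (LUNA16 dialect)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm", "solid_fraction"]


def write_annotations(anns: list[NoduleAnnotation], path: str | Path) -> None:
    """Write annotations as a LUNA16-dialect CSV (world mm, 6-decimal fixed)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for a in anns:
            x, y, z = a.center_world
            writer.writerow([a.scan_id, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}",
                             f"{a.diameter:.6f}",
                             "" if a.solid_fraction is None else f"{a.solid_fraction:.6f}"])


def read_annotations(path: str | Path) -> list[NoduleAnnotation]:
    """Read a LUNA16-dialect annotations CSV (solid_fraction column optional)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        frac = getattr(row, "solid_fraction", None)
        if frac is not None and pd.isna(frac):
            frac = None
        out.append(NoduleAnnotation(
            scan_id=str(row.seriesuid),
            center_world=(float(row.coordX), float(row.coordY), float(row.coordZ)),
            diameter=float(row.diameter_mm),
            solid_fraction=None if frac is None else float(frac)))
    return out


def write_cohort(phantoms: list[Phantom], out_dir: str | Path,
                 n_folds: int = 0) -> Path:
    """Write volumes, masks and annotations to disk; return the manifest path.

    The manifest CSV lists one row per scan: scan_id, volume/mask paths,
    and (when ``n_folds`` > 0) a round-robin fold id for cross-validation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    all_anns: list[NoduleAnnotation] = []
    for i, ph in enumerate(phantoms):
        vol_path = out_dir / f"{ph.volume.scan_id}.mhd"
        mask_path = out_dir / f"{ph.volume.scan_id}_mask.mhd"
        write_volume(ph.volume, vol_path)
        write_volume(CTVolume(ph.lung_mask.astype(np.uint8), ph.volume.spacing,
                              ph.volume.origin, ph.volume.scan_id), mask_path)
        all_anns.extend(ph.annotations)
        rows.append({"scan_id": ph.volume.scan_id, "volume": vol_path.name,
                     "mask": mask_path.name,
                     "fold": i % n_folds if n_folds else ""})
    write_annotations(all_anns, out_dir / "annotations.csv")
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["scan_id", "volume", "mask", "fold"]).to_csv(
        manifest, index=False)
    return manifest
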