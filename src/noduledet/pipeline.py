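"""Reproducible multi-stage runs tying all modules together.

Each stage is a pure function of (inputs on disk, config, seed): simulate a
phantom cohort, preprocess volumes, train a detector, detect on a cohort,
evaluate detections, and run the six-configuration pruning ladder that
compares backbone variants, the FPN neck and the two anchor-assignment
strategies on the same cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash, derive_seed, save_config
from .froc import CPMResult, crossval_aggregate, evaluate, write_metrics_report
from .inference import (compute_lung_mask, mask_filter, read_detections,
                        sliding_window_detect, write_detections)
from .model import RPN3D, build_model
from .phantom import generate_cohort, read_annotations, write_cohort
from .training import TrainResult, train
from .volume import Patch, preprocess, read_volume, sample_training_patches

log = logging.getLogger(__name__)


def _stage_banner(stage: str, cfg: RunConfig) -> float:
    log.info("stage=%s seed=%d config_hash=%s", stage, cfg.seed, config_hash(cfg))
    return time.perf_counter()


def _stage_done(stage: str, t0: float) -> None:
    log.info("stage=%s elapsed_s=%.2f", stage, time.perf_counter() - t0)


def run_simulate(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Generate a phantom cohort on disk; returns the manifest path."""
    t0 = _stage_banner("simulate", cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "run_config.yaml")
    if cfg.n_scans == 0:
        manifest = out_dir / "manifest.csv"
        pd.DataFrame(columns=["scan_id", "volume", "mask", "fold"]).to_csv(
            manifest, index=False)
        from .phantom import write_annotations
        write_annotations([], out_dir / "annotations.csv")
    else:
        phantoms = generate_cohort(cfg.phantom, cfg.n_scans,
                                   derive_seed(cfg.seed, "simulate"))
        manifest = write_cohort(phantoms, out_dir, n_folds=cfg.eval.n_folds)
    _stage_done("simulate", t0)
    return manifest


def _load_cohort(data_dir: Path, fold=None, exclude_fold=None):
    manifest = pd.read_csv(data_dir / "manifest.csv")
    if fold is not None:
        manifest = manifest[manifest["fold"] == fold]
    if exclude_fold is not None:
        manifest = manifest[manifest["fold"] != exclude_fold]
    anns = read_annotations(data_dir / "annotations.csv")
    by_scan = {}
    for a in anns:
        by_scan.setdefault(a.scan_id, []).append(a)
    return manifest, by_scan


def run_preprocess(cfg: RunConfig, data_dir: str | Path,
                   out_dir: str | Path) -> Path:
    """Resample + normalize every cohort volume; writes NIfTI outputs."""
    t0 = _stage_banner("preprocess", cfg)
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "run_config.yaml")
    manifest, _ = _load_cohort(data_dir)
    rows = []
    for row in manifest.itertuples(index=False):
        vol = read_volume(data_dir / row.volume)
        nvol = preprocess(vol, cfg.preprocess)
        from .volume import write_volume
        out_path = out_dir / f"{row.scan_id}_norm.nii.gz"
        write_volume(nvol, out_path)
        rows.append({"scan_id": row.scan_id, "volume": out_path.name})
    out = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    _stage_done("preprocess", t0)
    return out


def load_training_patches(cfg: RunConfig, data_dir: str | Path,
                          exclude_fold=None) -> list[Patch]:
    """Preprocess cohort volumes and sample training patches from each."""
    data_dir = Path(data_dir)
    manifest, anns_by_scan = _load_cohort(data_dir, exclude_fold=exclude_fold)
    patches: list[Patch] = []
    for row in manifest.itertuples(index=False):
        vol = read_volume(data_dir / row.volume)
        nvol = preprocess(vol, cfg.preprocess)
        mask = read_volume(data_dir / row.mask).voxels.astype(bool)
        patches.extend(sample_training_patches(
            nvol, anns_by_scan.get(row.scan_id, []), cfg.preprocess,
            seed=derive_seed(cfg.seed, f"patches:{row.scan_id}"),
            lung_mask=mask))
    return patches


def run_train(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path,
              exclude_fold=None) -> tuple[Path, TrainResult]:
    """Train a detector on a cohort; writes checkpoint + history CSV."""
    t0 = _stage_banner("train", cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "run_config.yaml")
    patches = load_training_patches(cfg, data_dir, exclude_fold=exclude_fold)
    model = build_model(replace(cfg.model, seed=derive_seed(cfg.seed, "model")))
    tcfg = replace(cfg.train, seed=derive_seed(cfg.seed, "train"))
    result = train(model, patches, tcfg, cfg.augment)
    ckpt = out_dir / "model.ckpt.npz"
    model.save(ckpt)
    pd.DataFrame(result.history).to_csv(out_dir / "history.csv", index=False)
    _stage_done("train", t0)
    return ckpt, result


def run_detect(cfg: RunConfig, data_dir: str | Path, checkpoint: str | Path,
               out_path: str | Path, fold=None) -> Path:
    """Detect nodules on every cohort scan; writes a detections CSV."""
    t0 = _stage_banner("detect", cfg)
    data_dir = Path(data_dir)
    model = RPN3D.load(checkpoint)
    manifest, _ = _load_cohort(data_dir, fold=fold)
    all_dets = []
    for row in manifest.itertuples(index=False):
        vol = read_volume(data_dir / row.volume)
        nvol = preprocess(vol, cfg.preprocess)
        dets = sliding_window_detect(nvol, model, cfg.inference)
        mask_name = getattr(row, "mask", None)
        mask_path = data_dir / mask_name if isinstance(mask_name, str) else None
        if mask_path is not None and mask_path.exists():
            mask = read_volume(mask_path).voxels.astype(bool)
        else:
            mask = compute_lung_mask(read_volume(data_dir / row.volume))
        dets = mask_filter(dets, mask)
        all_dets.extend(dets)
        log.info("scan=%s detections=%d", row.scan_id, len(dets))
    write_detections(all_dets, out_path)
    _stage_done("detect", t0)
    return Path(out_path)


def run_evaluate(cfg: RunConfig, detections_csv: str | Path,
                 annotations_csv: str | Path, out_path: str | Path,
                 scan_ids=None) -> CPMResult:
    """Score a detections CSV against annotations; writes the metrics report."""
    t0 = _stage_banner("evaluate", cfg)
    dets = read_detections(detections_csv)
    anns = read_annotations(annotations_csv)
    if scan_ids is not None:
        scan_ids = set(scan_ids)
        dets = [d for d in dets if d.scan_id in scan_ids]
        anns = [a for a in anns if a.scan_id in scan_ids]
    dets_by, anns_by = {}, {}
    for d in dets:
        dets_by.setdefault(d.scan_id, []).append(d)
    for a in anns:
        anns_by.setdefault(a.scan_id, []).append(a)
    result = evaluate(dets_by, anns_by, cfg.eval)
    write_metrics_report(result, out_path, cfg.eval.fp_rates)
    _stage_done("evaluate", t0)
    return result


def run_crossval(cfg: RunConfig, data_dir: str | Path,
                 out_dir: str | Path) -> CPMResult:
    """K-fold cross-validation: train on k-1 folds, test on the held-out one."""
    t0 = _stage_banner("crossval", cfg)
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    folds = sorted(manifest["fold"].unique())
    fold_results = []
    for f in folds:
        fold_dir = out_dir / f"fold_{f}"
        ckpt, _ = run_train(cfg, data_dir, fold_dir, exclude_fold=f)
        det_csv = run_detect(cfg, data_dir, ckpt, fold_dir / "detections.csv",
                             fold=f)
        scan_ids = manifest[manifest["fold"] == f]["scan_id"].astype(str)
        fold_results.append(run_evaluate(
            cfg, det_csv, data_dir / "annotations.csv",
            fold_dir / "metrics.csv", scan_ids=scan_ids))
    agg = crossval_aggregate(fold_results)
    write_metrics_report(agg, out_dir / "metrics.csv", cfg.eval.fp_rates)
    _stage_done("crossval", t0)
    return agg


# ---------------------------------------------------------------------------
# Pruning ladder
# ---------------------------------------------------------------------------

# (backbone, use_fpn, assignment used, assignment label shown)
LADDER_ROWS = (
    ("resnet", False, "iou", ""),
    ("resnext", False, "iou", ""),
    ("csp_resnext", False, "iou", ""),
    ("csp_resnext", True, "iou", ""),
    ("csp_resnext", True, "iou", "IoU matching"),
    ("csp_resnext", True, "nearest", "Nearest anchor"),
)


def run_prune_ladder(cfg: RunConfig, train_dir: str | Path,
                     test_dir: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """Train/evaluate the six ladder configurations on the same cohorts.

    Emits one row per configuration (backbone, FPN flag, anchor assignment,
    CPM); a failed leg is recorded with an error and the ladder continues.
    """
    t0 = _stage_banner("prune_ladder", cfg)
    train_dir, test_dir = Path(train_dir), Path(test_dir)
    patches = load_training_patches(cfg, train_dir)
    rows = []
    for backbone, use_fpn, assignment, label in LADDER_ROWS:
        leg = f"{backbone}{'+fpn' if use_fpn else ''}+{assignment}"
        try:
            model = build_model(replace(
                cfg.model, backbone_variant=backbone, use_fpn=use_fpn,
                seed=derive_seed(cfg.seed, "model")))
            tcfg = replace(cfg.train, assignment=assignment,
                           seed=derive_seed(cfg.seed, "train"))
            train(model, patches, tcfg, cfg.augment)
            tmp_ckpt = Path(out_csv).parent / f"ladder_{leg}.ckpt.npz"
            model.save(tmp_ckpt)
            det_csv = Path(out_csv).parent / f"ladder_{leg}_detections.csv"
            run_detect(cfg, test_dir, tmp_ckpt, det_csv)
            result = run_evaluate(cfg, det_csv, test_dir / "annotations.csv",
                                  Path(out_csv).parent / f"ladder_{leg}_metrics.csv")
            rows.append({"backbone": _display_name(backbone),
                         "fpn": "x" if use_fpn else "",
                         "anchor_assignment": label,
                         "cpm": round(result.cpm, 4)})
        except Exception as exc:   # noqa: BLE001 -- ladder must continue
            log.error("ladder leg %s failed: %s", leg, exc)
            rows.append({"backbone": _display_name(backbone),
                         "fpn": "x" if use_fpn else "",
                         "anchor_assignment": label,
                         "cpm": float("nan")})
    table = pd.DataFrame(rows, columns=["backbone", "fpn", "anchor_assignment", "cpm"])
    table.to_csv(out_csv, index=False)
    _stage_done("prune_ladder", t0)
    return table


def _display_name(backbone: str) -> str:
    return {"resnet": "ResNet", "resnext": "ResNeXt",
            "csp_resnext": "CSP-ResNeXt"}[backbone]
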