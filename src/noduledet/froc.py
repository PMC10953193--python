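"""FROC scoring and the competition performance metric (CPM).

Detections are matched to ground truth with the LUNA16-style hit criterion:
a detection is a true positive when its centre lies within the ground-truth
radius (diameter / 2) of a nodule centre.  Each nodule is credited once, to
its highest-probability hit; further hits on an already-credited nodule are
ignored (free-response convention; a flag turns them into false positives
instead).  The FROC curve sweeps the confidence threshold over all distinct
probabilities; sensitivities are read off at 0.125, 0.25, 0.5, 1, 2, 4 and
8 false positives per scan by linear interpolation, and the CPM is their
arithmetic mean.  Cross-validation folds are summarized as mean +/- sample
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import Detection
from .volume import NoduleAnnotation

FP_RATES = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class EvalConfig:
    fp_rates: tuple[float, ...] = FP_RATES
    n_folds: int = 10
    extra_hits_are_fp: bool = False

    def __post_init__(self) -> None:
        if len(self.fp_rates) != 7 or list(self.fp_rates) != sorted(self.fp_rates):
            raise ValueError("fp_rates must be the 7 rates, sorted ascending")


@dataclass
class LabeledDetection:
    probability: float
    is_tp: bool
    is_ignored: bool = False
    gt_index: int | None = None


@dataclass
class FROCCurve:
    # operating points, one per distinct threshold: (threshold, fp/scan, sensitivity)
    points: list[tuple[float, float, float]]
    n_scans: int
    n_nodules: int


@dataclass
class CPMResult:
    sensitivities: tuple[float, ...]
    cpm: float
    fold_cpms: list[float] = field(default_factory=list)
    mean: float | None = None
    sd: float | None = None


def match_detections(
    dets_per_scan: Mapping[str, Sequence[Detection]],
    gts_per_scan: Mapping[str, Sequence[NoduleAnnotation]],
    extra_hits_are_fp: bool = False,
) -> tuple[list[LabeledDetection], int]:
    """Label every detection TP/FP/ignored; returns labels and the gt count.

    Within each scan detections are visited by descending probability; the
    first detection within radius of an uncredited nodule credits it.
    """
    labeled: list[LabeledDetection] = []
    n_gts = 0
    scan_ids = set(dets_per_scan) | set(gts_per_scan)
    for scan_id in sorted(scan_ids):
        gts = list(gts_per_scan.get(scan_id, ()))
        n_gts += len(gts)
        centers = np.array([g.center_world for g in gts], dtype=float).reshape(-1, 3)
        radii = np.array([g.diameter / 2.0 for g in gts], dtype=float)
        credited = np.zeros(len(gts), dtype=bool)
        dets = sorted(dets_per_scan.get(scan_id, ()),
                      key=lambda d: -d.probability)
        for det in dets:
            if len(gts) == 0:
                labeled.append(LabeledDetection(det.probability, False))
                continue
            dist = np.linalg.norm(centers - np.asarray(det.center_world), axis=1)
            hit = dist <= radii
            fresh = hit & ~credited
            if fresh.any():
                j = int(np.nonzero(fresh)[0][np.argmin(dist[fresh])])
                credited[j] = True
                labeled.append(LabeledDetection(det.probability, True, gt_index=j))
            elif hit.any():
                labeled.append(LabeledDetection(det.probability, False,
                                                is_ignored=not extra_hits_are_fp))
            else:
                labeled.append(LabeledDetection(det.probability, False))
    return labeled, n_gts


def froc_curve(labeled: Sequence[LabeledDetection], n_scans: int,
               n_nodules: int) -> FROCCurve:
    """Build the FROC curve by sweeping over all distinct probabilities."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if n_nodules < 1:
        raise ValueError("sensitivity is undefined with zero nodules")
    active = [ld for ld in labeled if not ld.is_ignored]
    probs = np.array([ld.probability for ld in active], dtype=float)
    is_tp = np.array([ld.is_tp for ld in active], dtype=bool)
    order = np.argsort(-probs)
    probs, is_tp = probs[order], is_tp[order]
    points: list[tuple[float, float, float]] = []
    thresholds = np.unique(probs)[::-1]
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    for t in thresholds:
        k = int(np.searchsorted(-probs, -t, side="right"))
        points.append((float(t), float(fp_cum[k - 1]) / n_scans if k else 0.0,
                       float(tp_cum[k - 1]) / n_nodules if k else 0.0))
    return FROCCurve(points=points, n_scans=n_scans, n_nodules=n_nodules)


def sensitivity_at(curve: FROCCurve,
                   fp_rates: Sequence[float] = FP_RATES) -> np.ndarray:
    """Sensitivity at each requested FP/scan rate, linearly interpolated.

    Below the lowest achieved rate the curve is interpolated toward (0, 0);
    above the highest it is held at the rightmost sensitivity.  Where
    several thresholds share one FP rate the best sensitivity counts.
    """
    if not curve.points:
        return np.zeros(len(fp_rates))
    fps = np.array([p[1] for p in curve.points])
    sens = np.array([p[2] for p in curve.points])
    best: dict[float, float] = {}
    for f, s in zip(fps, sens):
        best[f] = max(best.get(f, 0.0), s)
    xs = np.array(sorted(best))
    ys = np.array([best[x] for x in xs])
    if xs[0] > 0.0:
        xs = np.insert(xs, 0, 0.0)
        ys = np.insert(ys, 0, 0.0)
    return np.interp(np.asarray(fp_rates, dtype=float), xs, ys)


def cpm(sensitivities: Sequence[float]) -> float:
    """Arithmetic mean of the seven per-rate sensitivities."""
    s = np.asarray(sensitivities, dtype=float)
    if s.shape != (7,):
        raise ValueError(f"exactly 7 sensitivities required, got shape {s.shape}")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("sensitivities must lie in [0, 1]")
    return float(s.mean())


def evaluate(
    dets_per_scan: Mapping[str, Sequence[Detection]],
    gts_per_scan: Mapping[str, Sequence[NoduleAnnotation]],
    cfg: EvalConfig | None = None,
) -> CPMResult:
    """Full single-split evaluation: match, FROC, 7 sensitivities, CPM."""
    cfg = cfg or EvalConfig()
    labeled, n_gts = match_detections(dets_per_scan, gts_per_scan,
                                      cfg.extra_hits_are_fp)
    n_scans = max(len(set(dets_per_scan) | set(gts_per_scan)), 1)
    curve = froc_curve(labeled, n_scans=n_scans, n_nodules=n_gts)
    sens = sensitivity_at(curve, cfg.fp_rates)
    return CPMResult(sensitivities=tuple(float(s) for s in sens), cpm=cpm(sens))


def crossval_aggregate(fold_results: Sequence[CPMResult]) -> CPMResult:
    """Aggregate per-fold CPM results as mean +/- sample SD.

    With a single fold the SD is reported as absent (None).
    """
    if not fold_results:
        raise ValueError("no folds to aggregate")
    cpms = [r.cpm for r in fold_results]
    sens = np.array([r.sensitivities for r in fold_results])
    mean_sens = sens.mean(axis=0)
    result = CPMResult(
        sensitivities=tuple(float(s) for s in mean_sens),
        cpm=float(np.mean(cpms)),
        fold_cpms=list(map(float, cpms)),
        mean=float(np.mean(cpms)),
        sd=float(np.std(cpms, ddof=1)) if len(cpms) >= 2 else None)
    return result


def write_metrics_report(result: CPMResult, path: str | Path,
                         fp_rates: Sequence[float] = FP_RATES) -> None:
    """Write per-rate sensitivities and CPM (plus fold stats) as CSV."""
    rows = [{"metric": f"sensitivity_at_{r:g}_fp", "value": s}
            for r, s in zip(fp_rates, result.sensitivities)]
    rows.append({"metric": "cpm", "value": result.cpm})
    if result.sd is not None:
        rows.append({"metric": "cpm_fold_mean", "value": result.mean})
        rows.append({"metric": "cpm_fold_sd", "value": result.sd})
    pd.DataFrame(rows).to_csv(path, index=False)
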