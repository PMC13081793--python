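"""Temporal-IoU matching and detection metrics.

A detection counts as a true positive when it is greedily matched
one-to-one (in descending confidence) to an unmatched ground-truth event of
the same class with temporal IoU >= 0.5.  Unmatched detections are false
positives; unmatched ground-truth events are false negatives.  Per class:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

Macro metrics are unweighted means over classes; micro metrics are computed
from pooled TP/FP/FN counts (never the mean of per-class F-scores).
Degenerate denominators yield 0 with a logged note rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchCounts",
    "MetricsReport",
    "temporal_iou",
    "match",
    "precision",
    "recall",
    "f_score",
    "report",
    "threshold_sweep",
    "overlap_density_experiment",
]

logger = logging.getLogger(__name__)


def temporal_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection-over-union of two time intervals, in [0, 1]."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("intervals must have positive length")
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


@dataclass
class MatchCounts:
    """Per-class TP/FP/FN tallies."""

    tp: dict[int, int]
    fp: dict[int, int]
    fn: dict[int, int]

    def classes(self) -> list[int]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))

    def add(self, other: "MatchCounts") -> "MatchCounts":
        out = MatchCounts(dict(self.tp), dict(self.fp), dict(self.fn))
        for d_self, d_other in (
            (out.tp, other.tp),
            (out.fp, other.fp),
            (out.fn, other.fn),
        ):
            for k, v in d_other.items():
                d_self[k] = d_self.get(k, 0) + v
        return out


def match(detections, ground_truth, iou_min: float = 0.5, classes=None) -> MatchCounts:
    """Greedy one-to-one matching of detections to ground-truth events.

    ``detections``: objects with class_id, t_start_s, t_end_s, confidence
    (already confidence-thresholded and NMS-filtered).
    ``ground_truth``: (class_id, t_start_s, t_end_s) tuples.
    Ties in confidence break by earlier start then lower class id.
    """
    class_ids = set(classes or [])
    class_ids.update(g[0] for g in ground_truth)
    class_ids.update(d.class_id for d in detections)
    tp = {c: 0 for c in class_ids}
    fp = {c: 0 for c in class_ids}
    fn = {c: 0 for c in class_ids}
    matched_gt = [False] * len(ground_truth)
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, d.t_start_s, d.class_id)
    )
    for det in ordered:
        best_iou, best_j = 0.0, -1
        for j, (gc, g0, g1) in enumerate(ground_truth):
            if matched_gt[j] or gc != det.class_id:
                continue
            iou = temporal_iou((det.t_start_s, det.t_end_s), (g0, g1))
            if iou >= iou_min and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched_gt[best_j] = True
            tp[det.class_id] += 1
        else:
            fp[det.class_id] += 1
    for j, (gc, _, _) in enumerate(ground_truth):
        if not matched_gt[j]:
            fn[gc] += 1
    return MatchCounts(tp, fp, fn)


def precision(tp: int, fp: int) -> float:
    if tp + fp == 0:
        logger.debug("precision undefined (no detections); returning 0")
        return 0.0
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    if tp + fn == 0:
        logger.debug("recall undefined (no ground truth); returning 0")
        return 0.0
    return tp / (tp + fn)


def f_score(p: float, r: float) -> float:
    if p + r == 0:
        logger.debug("F-score undefined (p + r = 0); returning 0")
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass
class MetricsReport:
    per_class: dict[int, dict[str, float]]  # precision/recall/f_score per class
    macro: dict[str, float]
    micro: dict[str, float]
    threshold: float

    def to_frame(self, class_names: dict[int, str] | None = None) -> pd.DataFrame:
        rows = []
        for cid, m in sorted(self.per_class.items()):
            name = class_names.get(cid, str(cid)) if class_names else str(cid)
            rows.append({"class": name, "threshold": self.threshold, **m})
        rows.append({"class": "macro", "threshold": self.threshold, **self.macro})
        rows.append({"class": "micro", "threshold": self.threshold, **self.micro})
        return pd.DataFrame(rows)


def report(counts: MatchCounts, threshold: float = 0.5) -> MetricsReport:
    """Per-class, macro (unweighted mean) and micro (pooled) P/R/F."""
    per_class = {}
    for c in counts.classes():
        p = precision(counts.tp.get(c, 0), counts.fp.get(c, 0))
        r = recall(counts.tp.get(c, 0), counts.fn.get(c, 0))
        per_class[c] = {"precision": p, "recall": r, "f_score": f_score(p, r)}
    macro = {
        key: float(np.mean([m[key] for m in per_class.values()])) if per_class else 0.0
        for key in ("precision", "recall", "f_score")
    }
    tp, fp, fn = (sum(d.values()) for d in (counts.tp, counts.fp, counts.fn))
    mp, mr = precision(tp, fp), recall(tp, fn)
    micro = {"precision": mp, "recall": mr, "f_score": f_score(mp, mr)}
    return MetricsReport(per_class, macro, micro, threshold)


def evaluate_detections(
    per_sample_detections: list[list],
    per_sample_ground_truth: list[list[tuple[int, float, float]]],
    threshold: float,
    classes=None,
) -> MetricsReport:
    """Match sample-by-sample, pool counts, and report."""
    total = MatchCounts({}, {}, {})
    for dets, gt in zip(per_sample_detections, per_sample_ground_truth):
        total = total.add(match(dets, gt, classes=classes))
    return report(total, threshold)


def threshold_sweep(
    per_sample_raw_detections: list[list],
    per_sample_ground_truth: list[list[tuple[int, float, float]]],
    thresholds: tuple[float, ...] = (0.2, 0.3, 0.4),
    nms_overlap: float = 0.5,
    classes=None,
) -> dict[float, MetricsReport]:
    """Re-threshold, re-NMS and re-match raw detections per threshold.

    ``per_sample_raw_detections`` must retain confidences and must NOT have
    been NMS-filtered (NMS runs after each thresholding here).
    """
    from .detector import nms  # local import to avoid a module cycle

    out = {}
    for thr in thresholds:
        dets = [
            nms([d for d in sample if d.confidence >= thr], nms_overlap)
            for sample in per_sample_raw_detections
        ]
        out[thr] = evaluate_detections(dets, per_sample_ground_truth, thr, classes)
    return out


def overlap_density_experiment(
    corpus_train,
    corpus_test,
    caps: tuple[int, ...] = (2, 3, 4),
    run_config=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Macro/micro F as a function of the concurrency cap.

    For each cap, overlap datasets of identical size are regenerated (their
    composition differs stochastically, only the cap is systematic), a model
    is trained at the configured scale, and the ensemble is evaluated.
    Returns a tidy one-row-per-cap table.
    """
    from .pipeline import RunConfig, train_and_evaluate_overlap

    cfg = run_config or RunConfig()
    rows = []
    for cap in caps:
        rep = train_and_evaluate_overlap(corpus_train, corpus_test, cap, cfg, seed)
        rows.append(
            {
                "max_concurrency": cap,
                "macro_f": rep.macro["f_score"],
                "micro_f": rep.micro["f_score"],
            }
        )
    return pd.DataFrame(rows)
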