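"""Segmentation evaluation: pixel metrics, per-nucleus detection, aggregation.

Pixel metrics are the standard confusion-count quintet

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)
    Jaccard   = TP / (TP + FP + FN)     Dice = 2*TP / (2*TP + FP + FN)

computed against a binary ground-truth mask.  Degenerate 0/0 cases follow
fixed conventions (centralized in ``pixel_metrics``) so aggregates never
contain silent NaNs.

Object-level evaluation follows the nuclei-detection-rate (NDR) rule: a
ground-truth nucleus counts as detected when the prediction covers strictly
more than ``detection_tau`` (default 60%) of its pixels.  The abnormal NDR is
the same statistic restricted to nuclei flagged abnormal in the scene
metadata.  NDR is recall-only by design — spurious predicted regions are
penalized by the pixel metrics, not here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .synthetic import NucleusSpec

__all__ = [
    "ConfusionCounts",
    "PixelMetrics",
    "NucleusRecord",
    "ImageResult",
    "EvaluationReport",
    "confusion_counts",
    "pixel_metrics",
    "per_nucleus_records",
    "aggregate_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class PixelMetrics:
    precision: float
    recall: float
    f_measure: float
    jaccard: float
    dice: float


@dataclass(frozen=True)
class NucleusRecord:
    gt_label: int
    area: int
    recall: float
    detected: bool
    abnormal: bool


@dataclass
class ImageResult:
    image_id: str
    method: str
    metrics: PixelMetrics | None
    nuclei: list[NucleusRecord] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Per-image results plus per-method dataset aggregates."""

    per_image: list[ImageResult]
    aggregates: pd.DataFrame    # one row per method

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for r in self.per_image:
            m = r.metrics
            rows.append({
                "image": r.image_id,
                "method": r.method,
                "precision": m.precision if m else np.nan,
                "recall": m.recall if m else np.nan,
                "f_measure": m.f_measure if m else np.nan,
                "jaccard": m.jaccard if m else np.nan,
                "dsc_percent": 100.0 * m.dice if m else np.nan,
                "n_nuclei": len(r.nuclei),
                "n_detected": sum(n.detected for n in r.nuclei),
                "n_abnormal": sum(n.abnormal for n in r.nuclei),
                "n_abnormal_detected": sum(n.detected for n in r.nuclei if n.abnormal),
            })
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_image": [
                {
                    "image": r.image_id,
                    "method": r.method,
                    "metrics": asdict(r.metrics) if r.metrics else None,
                    "nuclei": [asdict(n) for n in r.nuclei],
                }
                for r in self.per_image
            ],
            "aggregates": self.aggregates.reset_index()
                              .replace({np.nan: None}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted mask against ground truth."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def pixel_metrics(counts: ConfusionCounts) -> PixelMetrics:
    """The five pixel metrics, with explicit degenerate-case conventions:
    precision/recall are 0 when their denominator is 0, and a prediction that
    is vacuously perfect (tp = fp = fn = 0) scores 1 on all overlap metrics.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall > 0:
        f_measure = 2.0 * precision * recall / (precision + recall)
    else:
        f_measure = 0.0
    if tp + fp + fn == 0:
        jaccard = 1.0
        dice = 1.0
    else:
        jaccard = tp / (tp + fp + fn)
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
    return PixelMetrics(precision=precision, recall=recall, f_measure=f_measure,
                        jaccard=jaccard, dice=dice)


def per_nucleus_records(
    pred: np.ndarray,
    gt_labels: np.ndarray,
    metadata: list[NucleusSpec],
    detection_tau: float = 0.6,
) -> list[NucleusRecord]:
    """Per-ground-truth-nucleus coverage and detection flags.

    For each labeled region r: recall_r = |pred AND r| / |r|, and the nucleus
    is detected iff recall_r > detection_tau (strictly).  ``metadata[i]``
    must describe label i + 1; a label without metadata raises
    AnnotationError.
    """
    pred = np.asarray(pred, dtype=bool)
    gt_labels = np.asarray(gt_labels)
    if pred.shape != gt_labels.shape:
        raise ValueError("pred and gt_labels must share a shape")
    labels = np.unique(gt_labels)
    labels = labels[labels > 0]
    records = []
    for lab in labels:
        if lab > len(metadata):
            raise AnnotationError(f"label {lab} has no metadata entry")
        region = gt_labels == lab
        area = int(region.sum())
        covered = int((pred & region).sum())
        recall = covered / area
        records.append(NucleusRecord(
            gt_label=int(lab),
            area=area,
            recall=recall,
            detected=recall > detection_tau,
            abnormal=bool(metadata[lab - 1].abnormal),
        ))
    return records


def aggregate_report(results: list[ImageResult]) -> EvaluationReport:
    """Per-method macro averages of the pixel metrics plus pooled NDR.

    Pixel metrics are averaged per image then across images (macro mean);
    NDR pools detections over all nuclei of all images of a method.  With no
    abnormal nuclei in the dataset the abnormal NDR is reported as NaN (JSON
    null), never a crash.
    """
    if not results:
        raise ValueError("need at least one image result")
    rows = {}
    for r in results:
        rows.setdefault(r.method, []).append(r)
    agg_rows = []
    for method, items in rows.items():
        metric_list = [it.metrics for it in items if it.metrics is not None]
        nuclei = [n for it in items for n in it.nuclei]
        abnormal = [n for n in nuclei if n.abnormal]
        agg_rows.append({
            "method": method,
            "precision": float(np.mean([m.precision for m in metric_list])) if metric_list else np.nan,
            "recall": float(np.mean([m.recall for m in metric_list])) if metric_list else np.nan,
            "f_measure": float(np.mean([m.f_measure for m in metric_list])) if metric_list else np.nan,
            "jaccard": float(np.mean([m.jaccard for m in metric_list])) if metric_list else np.nan,
            "dice": float(np.mean([m.dice for m in metric_list])) if metric_list else np.nan,
            "n_images": len(items),
            "n_nuclei": len(nuclei),
            "ndr": (sum(n.detected for n in nuclei) / len(nuclei)) if nuclei else np.nan,
            "abnormal_ndr": (sum(n.detected for n in abnormal) / len(abnormal))
                            if abnormal else np.nan,
        })
    aggregates = pd.DataFrame(agg_rows).set_index("method")
    return EvaluationReport(per_image=list(results), aggregates=aggregates)
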