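"""Dataset-level evaluation: per-image metrics, aggregates, failures, overlays.

Metrics are computed per image at ground-truth native resolution and then
macro-averaged (the mean of per-image values), overall and per lesion class.
A segmentation is counted as a failure when its Jaccard index falls below
the usability cutoff (0.65), i.e. its Threshold Jaccard is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import resize_mask
from .metrics import (accuracy, confusion_counts, dice, jaccard,
                      threshold_jaccard)

METRIC_COLUMNS = ("dice", "jaccard", "threshold_jaccard", "accuracy")


@dataclass
class MetricReport:
    """Per-image metric rows plus overall/per-class macro averages."""

    per_image: pd.DataFrame           # id, class, dice, jaccard, threshold_jaccard, accuracy
    overall: dict[str, float]
    per_class: pd.DataFrame | None
    failures: list[str]               # ids with jaccard < threshold
    threshold: float

    def to_csv(self, path: str | Path) -> None:
        self.per_image.to_csv(Path(path), index=False)


def evaluate_dataset(predictions: Mapping[str, np.ndarray],
                     ground_truth: Mapping[str, np.ndarray],
                     labels: Mapping[str, str] | None = None,
                     threshold: float = 0.65) -> MetricReport:
    """Score predicted masks against ground truth, matched by image id.

    Predictions whose shape differs from the ground truth are resized to the
    ground-truth resolution (nearest-neighbour) before scoring.
    """
    pred_ids, gt_ids = set(predictions), set(ground_truth)
    if pred_ids != gt_ids:
        only_pred = sorted(pred_ids - gt_ids)
        only_gt = sorted(gt_ids - pred_ids)
        raise ValueError(
            f"prediction/ground-truth ids do not match; "
            f"only in predictions: {only_pred}; only in ground truth: {only_gt}")

    rows = []
    for image_id in sorted(ground_truth):
        gt = np.asarray(ground_truth[image_id])
        pred = np.asarray(predictions[image_id])
        if pred.shape != gt.shape:
            pred = resize_mask(pred, gt.shape)
        c = confusion_counts(pred, gt)
        j = jaccard(c)
        rows.append({
            "id": image_id,
            "class": labels.get(image_id) if labels else None,
            "dice": dice(c),
            "jaccard": j,
            "threshold_jaccard": threshold_jaccard(j, threshold),
            "accuracy": accuracy(c),
        })
    per_image = pd.DataFrame(rows)
    overall = {m: float(per_image[m].mean()) for m in METRIC_COLUMNS}
    failures = per_image.loc[per_image["jaccard"] < threshold, "id"].tolist()
    per_class = None
    if labels is not None:
        report = MetricReport(per_image, overall, None, failures, threshold)
        per_class = per_class_report(report, labels)
    return MetricReport(per_image, overall, per_class, failures, threshold)


def per_class_report(report: MetricReport,
                     labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-lesion-class macro averages (one row per class present)."""
    per_image = report.per_image.copy()
    missing = [i for i in per_image["id"] if i not in labels]
    if missing:
        raise ValueError(f"unlabeled image ids: {missing}")
    per_image["class"] = [labels[i] for i in per_image["id"]]
    grouped = per_image.groupby("class", sort=True)
    table = grouped[list(METRIC_COLUMNS)].mean()
    table.insert(0, "n", grouped.size())
    return table.reset_index()


# Fig-style overlay colouring: TP green, FP red, FN blue, TN black.
_OVERLAY = {
    "tp": np.array([0, 255, 0], dtype=np.uint8),
    "fp": np.array([255, 0, 0], dtype=np.uint8),
    "fn": np.array([0, 0, 255], dtype=np.uint8),
    "tn": np.array([0, 0, 0], dtype=np.uint8),
}


def comparison_image(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """RGB overlay of prediction vs ground truth (uint8, H x W x 3)."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    p, g = pred.astype(bool), gt.astype(bool)
    out = np.zeros((*pred.shape, 3), dtype=np.uint8)
    out[p & g] = _OVERLAY["tp"]
    out[p & ~g] = _OVERLAY["fp"]
    out[~p & g] = _OVERLAY["fn"]
    return out
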