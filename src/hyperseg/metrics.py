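"""Segmentation-quality and volumetry metrics.

Overlap metrics come from per-class TP/FP/FN counts; surface metrics (HD,
ASSD) use exact Euclidean distance transforms in millimetres; clinical
agreement uses Pearson correlation and Bland-Altman statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, UndefinedMetricError
from .losses import boundary_voxels

__all__ = [
    "MetricReport", "confusion_metrics", "hausdorff", "assd", "volume_ml",
    "bland_altman", "pearson_r", "evaluate_case", "FOREGROUND_CLASSES",
]

FOREGROUND_CLASSES = (1, 2)  # LA, EAT; background excluded from means
CLASS_NAMES = {0: "background", 1: "LA", 2: "EAT"}


@dataclass
class MetricReport:
    """Per-class and mean metric values for one case."""

    per_class: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)


def _counts(pred: np.ndarray, truth: np.ndarray, cls: int):
    p = pred == cls
    t = truth == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, fn


def confusion_metrics(pred: np.ndarray, truth: np.ndarray, cls: int):
    """(dice, iou, precision, recall, f1) for one class.

    Both masks empty -> all ones; exactly one empty -> all zeros.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp, fp, fn = _counts(pred, truth, cls)
    if tp == 0 and fp == 0 and fn == 0:
        return (1.0,) * 5
    if tp == 0 and (fp == 0 or fn == 0):
        return (0.0,) * 5
    dice = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return dice, iou, precision, recall, f1


def _surface_distances(a: np.ndarray, b: np.ndarray, spacing):
    """Directed distances (mm) from each surface voxel of ``a`` to the surface of ``b``."""
    sa, sb = boundary_voxels(a), boundary_voxels(b)
    dt = ndimage.distance_transform_edt(~sb, sampling=spacing)
    return dt[sa]


def hausdorff(a: np.ndarray, b: np.ndarray, spacing, percentile: float = 100.0) -> float:
    """Symmetric (max of directed) Hausdorff distance in mm; ``percentile``
    selects e.g. HD95.  Raises :class:`UndefinedMetricError` on empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise UndefinedMetricError("Hausdorff distance undefined for empty masks")
    dab = _surface_distances(a, b, spacing)
    dba = _surface_distances(b, a, spacing)
    if percentile >= 100.0:
        return float(max(dab.max(), dba.max()))
    return float(max(np.percentile(dab, percentile), np.percentile(dba, percentile)))


def assd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Average symmetric surface distance in mm (mean of the two directed means)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise UndefinedMetricError("ASSD undefined for empty masks")
    dab = _surface_distances(a, b, spacing)
    dba = _surface_distances(b, a, spacing)
    return float((dab.mean() + dba.mean()) / 2.0)


def volume_ml(mask: np.ndarray, spacing) -> float:
    """Voxel count x voxel volume (mm^3) / 1000."""
    voxel_mm3 = float(np.prod([float(s) for s in spacing]))
    return float(np.count_nonzero(mask) * voxel_mm3 / 1000.0)


def bland_altman(pairs):
    """(bias, loa_low, loa_high) for (reference, estimate) pairs.

    bias = mean(estimate - reference); limits = bias +/- 1.96 * SD (population
    SD, ddof=0, which is what makes differences {-1, 1} give limits +/-1.96).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise InputError("bland_altman needs at least 2 (reference, estimate) pairs")
    diff = pairs[:, 1] - pairs[:, 0]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r(pairs) -> float:
    """Pearson product-moment correlation of (reference, estimate) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise InputError("pearson_r needs at least 2 pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("Pearson correlation undefined for zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_case(pred: np.ndarray, truth: np.ndarray, spacing,
                  hd_percentile: float = 100.0) -> MetricReport:
    """Full per-case report over the foreground classes {LA, EAT}.

    Surface metrics that are undefined (a class empty in either mask) are
    reported as ``None`` rather than 0.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    report = MetricReport()
    for cls in FOREGROUND_CLASSES:
        name = CLASS_NAMES[cls]
        dice, iou, prec, rec, f1 = confusion_metrics(pred, truth, cls)
        entry = {"dice": dice, "iou": iou, "precision": prec,
                 "recall": rec, "f1": f1,
                 "volume_ml_pred": volume_ml(pred == cls, spacing),
                 "volume_ml_truth": volume_ml(truth == cls, spacing)}
        try:
            entry["hd"] = hausdorff(pred == cls, truth == cls, spacing, hd_percentile)
            entry["assd"] = assd(pred == cls, truth == cls, spacing)
        except UndefinedMetricError:
            entry["hd"] = None
            entry["assd"] = None
        report.per_class[name] = entry
    for key in ("dice", "iou", "precision", "recall", "f1", "hd", "assd"):
        vals = [report.per_class[CLASS_NAMES[c]][key] for c in FOREGROUND_CLASSES]
        vals = [v for v in vals if v is not None]
        report.mean[key] = float(np.mean(vals)) if vals else None
    return report
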