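"""Pixel confusion matrix and the mIoU / mPA summary metrics.

Rows index the true class, columns the predicted class.  Per class i,
IoU_i = p_ii / (sum_j p_ij + sum_j p_ji - p_ii) and PA_i = p_ii / sum_j p_ij;
the means run over all k+1 classes (background included by default), with
classes absent from both prediction and truth excluded (and logged).
"""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

IGNORE_LABEL = 255


class ConfusionMatrix:
    def __init__(self, num_classes: int):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.num_classes = num_classes
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def update(self, pred, truth, ignore_label: int = IGNORE_LABEL) -> "ConfusionMatrix":
        pred = np.asarray(pred).ravel()
        truth = np.asarray(truth).ravel()
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
        keep = truth != ignore_label
        pred, truth = pred[keep], truth[keep]
        k = self.num_classes
        if pred.size and (pred.min() < 0 or pred.max() >= k or
                          truth.min() < 0 or truth.max() >= k):
            raise ValueError(f"labels outside [0, {k})")
        self.counts += np.bincount(truth * k + pred, minlength=k * k).reshape(k, k)
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self):
        """(iou, pa, present) arrays; absent classes carry NaN."""
        c = self.counts.astype(np.float64)
        tp = np.diag(c)
        row = c.sum(axis=1)
        col = c.sum(axis=0)
        present = (row + col) > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            iou = np.where(present, tp / np.maximum(row + col - tp, 1e-300), np.nan)
            pa = np.where(row > 0, tp / np.maximum(row, 1e-300), np.nan)
        pa = np.where(present & (row == 0), 0.0, pa)  # predicted-only class: PA 0
        return iou, pa, present

    def save(self, path):
        np.savetxt(path, self.counts, fmt="%d")

    @classmethod
    def load(cls, path):
        counts = np.loadtxt(path, dtype=np.int64, ndmin=2)
        cm = cls(counts.shape[0])
        cm.counts[...] = counts
        return cm


def update_confusion(cm: ConfusionMatrix, pred, truth,
                     ignore_label: int = IGNORE_LABEL) -> ConfusionMatrix:
    return cm.update(pred, truth, ignore_label)


def miou_mpa(cm: ConfusionMatrix) -> tuple[float, float]:
    """(mIoU, mPA) in percent over the classes present in the matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    iou, pa, present = cm.per_class()
    absent = np.flatnonzero(~present)
    if absent.size:
        logger.info("classes excluded from the mean (absent): %s", absent.tolist())
    miou = float(np.nanmean(iou[present]) * 100.0)
    mpa = float(np.nanmean(pa[present]) * 100.0)
    return miou, mpa


def per_class_report(cm: ConfusionMatrix, class_names=None) -> str:
    """CSV text: class, IoU(%), PA(%)."""
    iou, pa, present = cm.per_class()
    names = class_names or [f"class_{i}" for i in range(cm.num_classes)]
    lines = ["class,iou_percent,pa_percent"]
    for i, name in enumerate(names):
        if present[i]:
            lines.append(f"{name},{100 * iou[i]:.2f},{100 * pa[i]:.2f}")
        else:
            lines.append(f"{name},absent,absent")
    miou, mpa = miou_mpa(cm)
    lines.append(f"mean,{miou:.2f},{mpa:.2f}")
    return "\n".join(lines)
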