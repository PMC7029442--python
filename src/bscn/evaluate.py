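"""Pixel-level segmentation evaluation.

Confusion counts, Se/Sp/Acc/Pr/F1, the Dice overlap, and ROC/AUC, per image
and pooled over a dataset.  Definitions: Se = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total, Pr = TP/(TP+FP), F1 = 2*Pr*Se/(Pr+Se),
Dice = 2|GT ∩ SR| / (|GT| + |SR|).  Aggregation pools raw counts across
images (not averages of per-image metrics) so pooled Acc is the accuracy
over the pooled pixel set.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics_from_counts",
    "dice_from_masks",
    "roc_auc",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __add__(self, other):
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)

    @property
    def total(self):
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    image_id: str
    Se: float
    Sp: float
    Acc: float
    Pr: float
    F1: float
    Dice: float
    AUC: float | None = None


def _check_binary(a, name):
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1, False, True))):
        raise ValueError(f"{name} must be binary, found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred, gt, mask=None) -> ConfusionCounts:
    """Pixel confusion counts, optionally restricted to mask == 1."""
    pred = _check_binary(pred, "pred")
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if mask is not None:
        mask = _check_binary(mask, "mask")
        pred, gt = pred[mask], gt[mask]
    return ConfusionCounts(
        TP=int(np.sum(pred & gt)),
        FP=int(np.sum(pred & ~gt)),
        TN=int(np.sum(~pred & ~gt)),
        FN=int(np.sum(~pred & gt)),
    )


def _safe_div(num, den, name):
    if den == 0:
        warnings.warn(f"{name}: 0/0 encountered; returning 0")
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts):
    """(Se, Sp, Acc, Pr, F1) from confusion counts; 0/0 -> 0 with warning."""
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    se = _safe_div(c.TP, c.TP + c.FN, "Se")
    sp = _safe_div(c.TN, c.TN + c.FP, "Sp")
    acc = (c.TP + c.TN) / c.total
    pr = _safe_div(c.TP, c.TP + c.FP, "Pr")
    f1 = _safe_div(2 * pr * se, pr + se, "F1")
    return se, sp, acc, pr, f1


def dice_from_masks(gt, pred):
    """Dice overlap of two binary masks; both-empty -> 1 by convention."""
    gt = _check_binary(gt, "gt")
    pred = _check_binary(pred, "pred")
    if gt.shape != pred.shape:
        raise ValueError("mask shapes differ")
    denom = int(gt.sum()) + int(pred.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(gt & pred)) / denom


def roc_auc(prob_map, gt, mask=None):
    """ROC curve and trapezoidal AUC of a probability map against binary gt.

    Returns ((fpr, tpr, thresholds), auc).  Raises if gt is single-class.
    """
    prob = np.asarray(prob_map, dtype=np.float64).ravel()
    gt = _check_binary(gt, "gt").ravel()
    if mask is not None:
        m = _check_binary(mask, "mask").ravel()
        prob, gt = prob[m], gt[m]
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if gt.all() or not gt.any():
        raise ValueError("ROC undefined: ground truth contains a single class")
    fpr, tpr, thr = _sk_roc_curve(gt.astype(int), prob)
    return (fpr, tpr, thr), float(_sk_auc(fpr, tpr))


def _report_from(pred_bin, gt, prob=None, mask=None, image_id="aggregate"):
    c = confusion_counts(pred_bin, gt, mask)
    se, sp, acc, pr, f1 = metrics_from_counts(c)
    if mask is not None:
        m = _check_binary(mask, "mask")
        dice = dice_from_masks(np.asarray(gt, bool)[m], np.asarray(pred_bin, bool)[m])
    else:
        dice = dice_from_masks(gt, pred_bin)
    auc_val = None
    if prob is not None:
        gt_flat = _check_binary(gt, "gt")
        single_class = gt_flat.all() or not gt_flat.any()
        if not single_class:
            _, auc_val = roc_auc(prob, gt, mask)
    return c, MetricsReport(image_id, se, sp, acc, pr, f1, dice, auc_val)


def evaluate_dataset(pred_dir, gt_dir, threshold=0.5, out_dir=None,
                     fov_dir=None):
    """Evaluate a directory of probability maps against ground-truth masks.

    Matches files by stem; probability maps are ``.npy`` arrays or 16-bit
    PNGs, labels any image format (binarised at > 0).  Returns (per-image
    reports, aggregate report, skipped ids); writes metrics.csv/.json when
    ``out_dir`` is given.
    """
    import imageio.v3 as iio

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    preds = {p.stem: p for p in sorted(pred_dir.iterdir())
             if p.suffix in (".npy", ".png", ".tif", ".tiff")}
    gts = {p.stem: p for p in sorted(gt_dir.iterdir())
           if p.suffix in (".npy", ".png", ".gif", ".tif", ".tiff", ".ppm")}
    shared = sorted(set(preds) & set(gts))
    skipped = sorted(set(preds) ^ set(gts))
    for s in skipped:
        warnings.warn(f"evaluate_dataset: unmatched id {s!r}; skipped")
    reports, pooled = [], ConfusionCounts(0, 0, 0, 0)
    pooled_prob, pooled_gt = [], []
    for stem in shared:
        p = preds[stem]
        if p.suffix == ".npy":
            prob = np.load(p).astype(np.float64)
        else:
            raw = iio.imread(p).astype(np.float64)
            prob = raw / (65535.0 if raw.max() > 255 else 255.0)
        g = gts[stem]
        gt = (np.load(g) if g.suffix == ".npy" else iio.imread(g)) > 0
        if gt.ndim == 3:
            gt = gt[..., 0]
        if prob.shape != gt.shape:
            raise ValueError(f"{stem}: prediction {prob.shape} vs gt {gt.shape}")
        mask = None
        if fov_dir is not None:
            fp = Path(fov_dir) / f"{stem}.png"
            if fp.exists():
                mask = iio.imread(fp) > 0
                if mask.ndim == 3:
                    mask = mask[..., 0]
        c, rep = _report_from(prob >= threshold, gt, prob, mask, stem)
        reports.append(rep)
        pooled = pooled + c
        flat_prob = prob[mask] if mask is not None else prob.ravel()
        flat_gt = gt[mask] if mask is not None else gt.ravel()
        pooled_prob.append(flat_prob.ravel())
        pooled_gt.append(flat_gt.ravel())
    if shared:
        prob_all = np.concatenate(pooled_prob)
        gt_all = np.concatenate(pooled_gt)
        se, sp, acc, pr, f1 = metrics_from_counts(pooled)
        dice = _safe_div(2 * pooled.TP, 2 * pooled.TP + pooled.FP + pooled.FN,
                         "Dice")
        auc_val = None
        if gt_all.any() and not gt_all.all():
            _, auc_val = roc_auc(prob_all, gt_all)
        aggregate = MetricsReport("aggregate", se, sp, acc, pr, f1, dice, auc_val)
    else:
        aggregate = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [asdict(r) for r in reports]
        if aggregate:
            rows.append(asdict(aggregate))
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(MetricsReport(
                "x", 0, 0, 0, 0, 0, 0).__dict__))
            writer.writeheader()
            writer.writerows(rows)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump({"per_image": rows[:-1] if aggregate else rows,
                       "aggregate": asdict(aggregate) if aggregate else None,
                       "skipped": skipped}, fh, indent=2)
    return reports, aggregate, skipped
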