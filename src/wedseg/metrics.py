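"""Segmentation metrics: per-class IoU, Dice, dataset pixel accuracy.

IoU_k counts pixels where prediction and truth both equal k over pixels
where either does; Dice is the per-class binary overlap 2|A∩B|/(|A|+|B|)
macro-averaged over classes present in either mask (the two are linked by
dice = 2·IoU/(1+IoU)); dataset accuracy pools correct pixels over all
images.  When a class is absent from both masks its IoU/Dice is 1.0 by
convention and the class is excluded from the means, so background-only
tiles do not contribute spurious zeros.

``threshold_refine`` applies the post-hoc probability threshold (default
T = 0.35, strict inequality) to the nucleus-class channel on top of the
argmax labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricsReport", "confusion_matrix", "per_class_iou", "dice_coefficient",
    "dice_macro", "mean_iou_pooled", "dice_macro_pooled",
    "dataset_pixel_accuracy", "threshold_refine", "evaluate_dataset",
]

DEFAULT_THRESHOLD = 0.35
NUCLEUS_CLASS = 1


@dataclass(frozen=True)
class MetricsReport:
    """Aggregated scores for a prediction set (all values in [0,1])."""

    iou_per_class: tuple[float, ...]
    mean_iou: float
    dice_macro: float
    pixel_accuracy: float
    n_images: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["iou_per_class"] = list(self.iou_per_class)
        return d


def _check_pair(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    return pred, true


def confusion_matrix(pred, true, num_classes: int = 3) -> np.ndarray:
    """num_classes x num_classes counts, rows = truth, cols = prediction."""
    pred, true = _check_pair(pred, true)
    idx = true.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64)
    return np.bincount(idx, minlength=num_classes ** 2).reshape(num_classes, num_classes)


def per_class_iou(pred, true, k: int, empty_value: float = 1.0) -> float:
    """Intersection over union of the class-k indicator grids."""
    pred, true = _check_pair(pred, true)
    p, t = pred == k, true == k
    union = np.logical_or(p, t).sum()
    if union == 0:
        return empty_value
    return float(np.logical_and(p, t).sum() / union)


def dice_coefficient(pred, true, k: int, empty_value: float = 1.0) -> float:
    """Binary dice 2|A∩B|/(|A|+|B|) of the class-k indicator grids."""
    pred, true = _check_pair(pred, true)
    p, t = pred == k, true == k
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return empty_value
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def _present_classes(pred, true, num_classes):
    return [k for k in range(num_classes)
            if ((pred == k).any() or (true == k).any())]


def dice_macro(pred, true, num_classes: int = 3) -> float:
    """Mean dice over classes present in either mask."""
    pred, true = _check_pair(pred, true)
    present = _present_classes(pred, true, num_classes)
    if not present:
        return 1.0
    return float(np.mean([dice_coefficient(pred, true, k) for k in present]))


def _pooled_counts(preds, truths, num_classes):
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    for p, t in zip(preds, truths):
        cm += confusion_matrix(p, t, num_classes)
    tp = np.diag(cm).astype(np.float64)
    pred_tot = cm.sum(axis=0).astype(np.float64)
    true_tot = cm.sum(axis=1).astype(np.float64)
    return cm, tp, pred_tot, true_tot


def mean_iou_pooled(preds, truths, num_classes: int = 3) -> float:
    """Micro-pooled IoU averaged over classes present anywhere."""
    _, tp, pred_tot, true_tot = _pooled_counts(preds, truths, num_classes)
    union = pred_tot + true_tot - tp
    present = union > 0
    if not present.any():
        return 1.0
    return float((tp[present] / union[present]).mean())


def dice_macro_pooled(preds, truths, num_classes: int = 3) -> float:
    """Micro-pooled per-class dice, macro-averaged over present classes."""
    _, tp, pred_tot, true_tot = _pooled_counts(preds, truths, num_classes)
    denom = pred_tot + true_tot
    present = denom > 0
    if not present.any():
        return 1.0
    return float((2.0 * tp[present] / denom[present]).mean())


def dataset_pixel_accuracy(preds, truths) -> float:
    """Correct pixels over total pixels, pooled across the whole dataset."""
    if len(preds) != len(truths):
        raise ValueError(f"length mismatch {len(preds)} vs {len(truths)}")
    correct = total = 0
    for p, t in zip(preds, truths):
        p, t = _check_pair(p, t)
        correct += int((p == t).sum())
        total += p.size
    if total == 0:
        raise ValueError("no pixels to score")
    return correct / total


def threshold_refine(prob: np.ndarray, threshold: float = DEFAULT_THRESHOLD
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels plus a thresholded nucleus-probability binary mask.

    ``prob`` is (C, H, W) with per-pixel channel sums of 1.  The binary
    mask is (nucleus-class probability > threshold), strict.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    prob = np.asarray(prob)
    if prob.ndim != 3:
        raise ValueError(f"expected (C,H,W) probability map, got {prob.shape}")
    sums = prob.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("probability channels must sum to 1 per pixel")
    labels = prob.argmax(axis=0).astype(np.uint8)
    nuclei_binary = (prob[NUCLEUS_CLASS] > threshold).astype(np.uint8)
    return labels, nuclei_binary


def evaluate_dataset(net, images, truths, threshold: float = DEFAULT_THRESHOLD,
                     batch_size: int = 16) -> MetricsReport:
    """Predict, refine, and score a labeled dataset.

    IoU and accuracy pool pixel counts across all images (micro); dice is
    pooled per class then macro-averaged.
    """
    from .train import predict_batch

    if len(images) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if len(images) != len(truths):
        raise ValueError("images and truths must align")
    probs = predict_batch(net, images, batch_size=batch_size)
    preds = [threshold_refine(p, threshold)[0] for p in probs]
    num_classes = probs.shape[1]
    _, tp, pred_tot, true_tot = _pooled_counts(preds, truths, num_classes)
    union = pred_tot + true_tot - tp
    iou = np.where(union > 0, tp / np.maximum(union, 1), 1.0)
    present = union > 0
    return MetricsReport(
        iou_per_class=tuple(float(v) for v in iou),
        mean_iou=float(iou[present].mean()) if present.any() else 1.0,
        dice_macro=dice_macro_pooled(preds, truths, num_classes),
        pixel_accuracy=dataset_pixel_accuracy(preds, truths),
        n_images=len(images),
    )
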