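"""Per-class ROC/AUC, thresholded confusion metrics and activation heatmaps.

AUC is the area under the ROC curve obtained by sweeping every score
threshold (equal scores grouped), integrated by the trapezoid rule; it equals
the probability that a positive sample outscores a negative one, ties counted
one half.  Confusion metrics at a fixed threshold follow the standard
definitions:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = TP / (TP + FN)            (= TPR)
    specificity = TN / (FP + TN)            (= 1 - FPR)
    F1          = 2 TP / (2 TP + FP + FN)

Macro aggregation averages each metric over classes; classes with degenerate
denominators are excluded from the macro mean with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


class UndefinedMetricError(ValueError):
    pass


def roc_auc(scores, labels):
    """ROC points (fpr, tpr arrays) and AUC for one binary problem."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D vectors")
    pos = int((labels == 1).sum())
    if pos == 0 or pos == labels.size:
        raise UndefinedMetricError(
            f"ROC undefined: labels contain only the "
            f"{'positive' if pos else 'negative'} class"
        )
    fpr, tpr, _ = _roc_curve(labels, scores, drop_intermediate=False)
    return (fpr, tpr), float(_trapezoid_auc(fpr, tpr))


def confusion_counts(scores, labels, threshold: float = 0.5):
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels) == 1
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, fn, tn


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Accuracy / sensitivity / specificity / F1 for one class at a threshold.

    Degenerate denominators yield ``nan`` for the affected metric.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    tp, fp, fn, tn = confusion_counts(scores, labels, threshold)
    total = tp + fp + fn + tn

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return dict(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=ratio(tp + tn, total),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, fp + tn),
        f1=ratio(2 * tp, 2 * tp + fp + fn),
        threshold=threshold,
    )


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class_auc: np.ndarray
    mean_auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    threshold: float
    per_class: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(
            class_names=self.class_names,
            per_class_auc=[float(a) for a in self.per_class_auc],
            mean_auc=float(self.mean_auc),
            accuracy=float(self.accuracy),
            sensitivity=float(self.sensitivity),
            specificity=float(self.specificity),
            f1=float(self.f1),
            threshold=float(self.threshold),
        )


def evaluate_scores(scores, labels, class_names=None,
                    threshold: float = 0.5) -> MetricsReport:
    """Full multi-label report: per-class AUC + macro confusion metrics."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 2:
        raise ValueError("scores/labels must be matching (m, N) matrices")
    n = scores.shape[1]
    names = list(class_names) if class_names else [f"class{i}" for i in range(n)]
    aucs, rows = [], []
    for j in range(n):
        try:
            _, a = roc_auc(scores[:, j], labels[:, j])
        except UndefinedMetricError:
            warnings.warn(f"AUC undefined for {names[j]}; excluded from mean")
            a = float("nan")
        row = confusion_metrics(scores[:, j], labels[:, j], threshold)
        aucs.append(a)
        rows.append(row)

    def macro(key):
        vals = np.array([r[key] for r in rows], dtype=np.float64)
        if np.isnan(vals).any():
            warnings.warn(f"{key} undefined for some classes; macro over rest")
        return float(np.nanmean(vals))

    aucs = np.array(aucs)
    return MetricsReport(
        class_names=names,
        per_class_auc=aucs,
        mean_auc=float(np.nanmean(aucs)),
        accuracy=macro("accuracy"),
        sensitivity=macro("sensitivity"),
        specificity=macro("specificity"),
        f1=macro("f1"),
        threshold=threshold,
        per_class=rows,
    )


def save_roc_curves(scores, labels, class_names, path):
    """Plot per-class ROC curves (and the chance diagonal) to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    for j, name in enumerate(class_names):
        try:
            (fpr, tpr), a = roc_auc(scores[:, j], labels[:, j])
        except UndefinedMetricError:
            continue
        ax.plot(fpr, tpr, lw=1, label=f"{name} ({a:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=6, loc="lower right")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def activation_heatmap(network, image, layer: str = "highres"):
    """Spatial attention map from a late convolutional feature map.

    The channel-wise maximum of absolute activations at each position is
    min-max normalized to [0,1] and bilinearly upsampled to the input size.
    ``layer`` selects which map counts as "last": ``highres`` (default) takes
    the final high-resolution stream after the last fusion — the
    representation this architecture maintains precisely so that spatial
    detail survives to the end — while ``head`` takes the low-resolution
    2048-channel head convolution.  A constant activation map degenerates to
    all zeros.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    capture: dict = {}
    network.eval()
    network.forward(image, capture=capture)
    if layer == "highres":
        act = capture["streams"][0]
    elif layer == "head":
        act = capture["last_conv"]
    else:
        raise ValueError(f"unknown heatmap layer {layer!r}")
    if act is None:
        raise ValueError("network did not expose a convolutional activation")
    act = np.abs(act[0])                       # (C, h, w)
    hm = act.max(axis=0)
    span = hm.max() - hm.min()
    hm = (hm - hm.min()) / span if span > 0 else np.zeros_like(hm)
    zoom = (image.shape[2] / hm.shape[0], image.shape[3] / hm.shape[1])
    up = ndimage.zoom(hm, zoom, order=1)
    return np.clip(up, 0.0, 1.0)


def heatmap_box_mass(heatmap, boxes) -> tuple[float, float]:
    """Fraction of heatmap mass inside boxes vs the boxes' area fraction.

    ``boxes``: iterable of (x0, y0, x1, y1) pixel rectangles (end-exclusive).
    Returns (mass_fraction, area_fraction); localization beats chance when
    the first exceeds the second.
    """
    hm = np.asarray(heatmap, dtype=np.float64)
    mask = np.zeros_like(hm, dtype=bool)
    for x0, y0, x1, y1 in boxes:
        mask[int(y0):int(y1), int(x0):int(x1)] = True
    total = hm.sum()
    mass = float(hm[mask].sum() / total) if total > 0 else 0.0
    return mass, float(mask.mean())
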