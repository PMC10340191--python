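"""Focal loss and its class-difficulty-weighted variant.

The multi-label objective treats each of the N pathology outputs as an
independent binary problem.  The focal loss down-weights easy examples:

    FL(p, y=1) = -alpha     * (1 - p)^gamma * ln(p)
    FL(p, y=0) = -(1-alpha) *      p ^gamma * ln(1 - p)

with the class-balance factor ``alpha`` (default 0.25) and focusing exponent
``gamma`` (default 2).  The weighted focal loss multiplies each class's focal
term by a weight proportional to the inverse of that class's classification
accuracy from the previous training round, normalized to sum to one, so the
network shifts capacity toward the diseases it currently classifies worst.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

EPS = 1e-7          # probability clamp for the logarithms
ACC_FLOOR = 0.05    # accuracy floor preventing unbounded weights

log = logging.getLogger(__name__)


@dataclass
class ClassWeights:
    """Per-class loss weights (sum to 1) and the accuracies they came from."""

    w: np.ndarray
    accuracy_source: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        self.accuracy_source = np.asarray(self.accuracy_source, dtype=np.float64)
        if np.any(self.w <= 0):
            raise ValueError("class weights must be strictly positive")

    @classmethod
    def uniform(cls, n: int) -> "ClassWeights":
        return cls(np.full(n, 1.0 / n), np.ones(n))


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def focal_loss(p, y, alpha_balance: float = 0.25, gamma: float = 2.0):
    """Elementwise focal loss; ``p`` in (0,1) (clamped), ``y`` in {0,1}."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    pos = -alpha_balance * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - alpha_balance) * p ** gamma * np.log(1.0 - p)
    return np.where(y == 1, pos, neg)


def focal_loss_grad(p, y, alpha_balance: float = 0.25, gamma: float = 2.0):
    """d FL / d p, elementwise (zero outside the clamp range)."""
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    q = 1.0 - p
    dpos = alpha_balance * (gamma * q ** (gamma - 1.0) * np.log(p) - q ** gamma / p)
    dneg = (1.0 - alpha_balance) * (
        -gamma * p ** (gamma - 1.0) * np.log(1.0 - p) + p ** gamma / q
    )
    return np.where(y == 1, dpos, dneg)


def class_weights(accuracies) -> ClassWeights:
    """Inverse-accuracy weights, normalized to sum to one.

    Accuracies at or below zero are floored (with a logged warning) at
    ``ACC_FLOOR`` so early-training rounds cannot blow the weights up.
    """
    acc = np.asarray(accuracies, dtype=np.float64).copy()
    if acc.ndim != 1 or acc.size == 0:
        raise ValueError("accuracies must be a non-empty 1-D vector")
    if np.any(acc < ACC_FLOOR):
        log.warning(
            "flooring %d accuracy value(s) below %.2f", int((acc < ACC_FLOOR).sum()),
            ACC_FLOOR,
        )
        acc = np.maximum(acc, ACC_FLOOR)
    inv = 1.0 / acc
    return ClassWeights(inv / inv.sum(), acc)


def weighted_focal_loss(P, Y, weights: ClassWeights | None = None,
                        alpha_balance: float = 0.25, gamma: float = 2.0,
                        rescale_n: bool = False) -> float:
    """Mean over the batch of the weighted per-class focal-loss sum.

    With uniform weights this equals the plain summed focal loss divided by N.
    ``rescale_n`` multiplies the normalized weights by N so their mean is 1.
    """
    P = np.asarray(P, dtype=np.float64)
    Y = np.asarray(Y)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Y {Y.shape}")
    n = P.shape[1]
    w = ClassWeights.uniform(n).w if weights is None else weights.w
    if w.shape[0] != n:
        raise ValueError(f"expected {n} class weights, got {w.shape[0]}")
    scale = n if rescale_n else 1.0
    fl = focal_loss(P, Y, alpha_balance, gamma)
    return float((fl * w[None, :] * scale).sum(axis=1).mean())


def weighted_focal_loss_grad(P, Y, weights: ClassWeights | None = None,
                             alpha_balance: float = 0.25, gamma: float = 2.0,
                             rescale_n: bool = False) -> np.ndarray:
    """Gradient of :func:`weighted_focal_loss` with respect to ``P``."""
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[1]
    w = ClassWeights.uniform(n).w if weights is None else weights.w
    scale = n if rescale_n else 1.0
    g = focal_loss_grad(P, Y, alpha_balance, gamma)
    inside = (P > EPS) & (P < 1.0 - EPS)
    return (g * w[None, :] * scale * inside / P.shape[0]).astype(np.float32)


def update_weights(epoch_metrics, num_classes: int) -> ClassWeights:
    """Per-epoch weight refresh from last-round per-class accuracies.

    The first epoch has no previous round; call with ``None`` to get the
    uniform initialization.  Empty metrics fall back to uniform with a
    warning.
    """
    if epoch_metrics is None:
        return ClassWeights.uniform(num_classes)
    acc = np.asarray(epoch_metrics, dtype=np.float64)
    if acc.size == 0:
        warnings.warn("empty epoch metrics; falling back to uniform weights")
        return ClassWeights.uniform(num_classes)
    if acc.size != num_classes:
        raise ValueError(f"expected {num_classes} accuracies, got {acc.size}")
    return class_weights(acc)
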