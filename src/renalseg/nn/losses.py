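"""Segmentation losses: voxelwise cross-entropy and soft multi-class Dice.

The default training loss is their sum, the de-facto standard for organ and
lesion segmentation.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


def one_hot(target: np.ndarray, num_classes: int) -> np.ndarray:
    """(N,H,W) int array -> (N,C,H,W) float one-hot."""
    out = np.zeros((target.shape[0], num_classes) + target.shape[1:], dtype=T.DTYPE)
    n, h, w = np.indices(target.shape)
    out[n, target, h, w] = 1.0
    return out


def cross_entropy(logits: Tensor, target: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Mean voxelwise cross-entropy; ``target`` holds integer class indices.

    ``class_weights`` (length num_classes) rescales each voxel's loss by the
    weight of its true class, normalized by the total weight in the batch.
    """
    num_classes = logits.shape[1]
    oh = one_hot(target, num_classes)
    ls = T.log_softmax(logits, axis=1)
    if class_weights is None:
        return T.mul(T.tsum(T.mul(ls, oh)), -1.0 / target.size)
    w = np.asarray(class_weights, dtype=T.DTYPE)[target]  # (N,H,W)
    total = float(w.sum())
    return T.mul(T.tsum(T.mul(ls, oh * w[:, None])), -1.0 / max(total, 1e-12))


def balanced_class_weights(targets: np.ndarray, num_classes: int,
                           power: float = 0.5, clip: float = 20.0) -> np.ndarray:
    """Inverse-frequency weights, tempered by ``power`` and clipped.

    Tempering keeps very rare classes (lesions occupy a tiny voxel fraction)
    from dominating the loss entirely.
    """
    counts = np.bincount(targets.reshape(-1), minlength=num_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = (targets.size / (num_classes * counts)) ** power
    return np.clip(w / w.min(), 1.0, clip)


def soft_dice_loss(logits: Tensor, target: np.ndarray, smooth: float = 1.0,
                   include_background: bool = False) -> Tensor:
    """1 - mean soft Dice over (foreground) classes, batch pooled."""
    num_classes = logits.shape[1]
    oh = one_hot(target, num_classes)
    probs = T.softmax(logits, axis=1)
    start = 0 if include_background else 1
    dice_terms = []
    for c in range(start, num_classes):
        pc = T.narrow(probs, 1, c, 1)
        yc = oh[:, c:c + 1]
        inter = T.tsum(T.mul(pc, yc))
        den = T.add(T.tsum(pc), float(yc.sum()))
        dice_terms.append(T.div(T.add(T.mul(inter, 2.0), smooth), T.add(den, smooth)))
    total = dice_terms[0]
    for t in dice_terms[1:]:
        total = T.add(total, t)
    return T.add(1.0, T.mul(total, -1.0 / len(dice_terms)))


def ce_dice_loss(logits: Tensor, target: np.ndarray,
                 class_weights: np.ndarray | None = None) -> Tensor:
    return T.add(cross_entropy(logits, target, class_weights=class_weights),
                 soft_dice_loss(logits, target))


LOSSES = {
    "ce": cross_entropy,
    "dice": soft_dice_loss,
    "ce_dice": ce_dice_loss,
}
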