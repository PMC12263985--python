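"""Training losses: distance-weighted Dice, weighted cross-entropy,
curvature and Euclidean-weight regularizers, and their weighted sum.

Every loss is written against an ``xp`` namespace so the same code path
evaluates on plain numpy arrays (unit tests, oracles) and on
:mod:`hyperseg.tensor` graphs (training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import tensor as T
from .errors import InputError

SMOOTH = 1e-6

__all__ = [
    "DistanceWeightMap", "LossWeights", "inverse_distance_weights",
    "idwh_loss", "soft_dice_loss", "hmlr_cross_entropy",
    "inverse_prevalence_weights", "curvature_penalty",
    "euclidean_weight_penalty", "combined_loss", "log_softmax",
]


@dataclass
class LossWeights:
    """Coefficients of the composite loss (alpha*CE + gamma*curv + delta*IDWH + eps*L2)."""

    alpha: float = 0.5
    gamma: float = 0.2
    delta: float = 0.5
    epsilon: float = 0.2

    def __post_init__(self):
        for name in ("alpha", "gamma", "delta", "epsilon"):
            if getattr(self, name) < 0:
                raise InputError(f"loss weight {name} must be >= 0")


@dataclass
class DistanceWeightMap:
    """Per-voxel positive weights, maximal on the LA boundary surface."""

    weights: np.ndarray
    source_mask: np.ndarray
    spacing: tuple


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Surface voxels of a binary mask: mask voxels with a 6-neighbour outside."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=1)
    return mask & ~eroded


def inverse_distance_weights(la_mask: np.ndarray, spacing,
                             law: str = "inv", tau: float = 5.0) -> DistanceWeightMap:
    """Weights 1/(1+d) from the Euclidean distance (mm) to the LA boundary,
    normalized to mean 1 over the grid; empty mask -> uniform 1.

    ``law`` selects the decay: ``inv`` 1/(1+d), ``inv2`` 1/(1+d)^2,
    ``exp`` exp(-d/tau).
    """
    la_mask = np.asarray(la_mask, dtype=bool)
    spacing = tuple(float(s) for s in spacing)
    if not la_mask.any():
        return DistanceWeightMap(np.ones(la_mask.shape), la_mask, spacing)
    surf = boundary_voxels(la_mask)
    d = ndimage.distance_transform_edt(~surf, sampling=spacing)
    if law == "inv":
        w = 1.0 / (1.0 + d)
    elif law == "inv2":
        w = 1.0 / (1.0 + d) ** 2
    elif law == "exp":
        w = np.exp(-d / tau)
    else:
        raise InputError(f"unknown weight law {law!r}")
    w = w / w.mean()
    return DistanceWeightMap(w, la_mask, spacing)


def _as_weights(w) -> np.ndarray:
    return w.weights if isinstance(w, DistanceWeightMap) else np.asarray(w)


def idwh_loss(pred, target, weights=None, xp=np):
    """Distance-weighted multi-class soft Dice loss in [0, 1].

    ``pred``: per-voxel class probabilities, class-first ``(C, ...)``;
    ``target``: one-hot with the same shape; ``weights``: per-voxel map
    broadcastable over the spatial grid (``None`` -> uniform, reducing to
    the standard soft Dice loss).
    """
    pred_shape = pred.shape if not isinstance(pred, T.Tensor) else pred.data.shape
    tgt = np.asarray(target.data if isinstance(target, T.Tensor) else target)
    if tuple(pred_shape) != tgt.shape:
        raise InputError(f"pred shape {tuple(pred_shape)} != target shape {tgt.shape}")
    c = pred_shape[0]
    d = 1.0 if weights is None else _as_weights(weights)
    axes = tuple(range(1, len(pred_shape)))
    num = 2.0 * xp.sum(pred * tgt * d, axis=axes) + SMOOTH
    den = xp.sum(pred * pred * d, axis=axes) + xp.sum(tgt * tgt * d, axis=axes) + SMOOTH
    dice = xp.sum(num / den) / c
    return 1.0 - dice


def soft_dice_loss(pred, target, xp=np):
    """Standard multi-class soft Dice loss (uniform weights)."""
    return idwh_loss(pred, target, None, xp=xp)


def log_softmax(logits, xp=np):
    """Class-first log-softmax, numerically stabilized with a detached max."""
    if isinstance(logits, T.Tensor):
        m = logits.data.max(axis=0, keepdims=True)
    else:
        m = logits.max(axis=0, keepdims=True)
    s = logits - m
    return s - xp.log(xp.sum(xp.exp(s), axis=0, keepdims=True))


def inverse_prevalence_weights(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/prevalence, mean-normalized to 1
    over the classes present in ``labels``; absent classes get weight 0."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel(), minlength=num_classes).astype(float)
    w = np.zeros(num_classes)
    present = counts > 0
    w[present] = labels.size / counts[present]
    if present.any():
        w[present] /= w[present].mean()
    return w


def hmlr_cross_entropy(logits, target: np.ndarray, class_weights=None, xp=np):
    """Weighted negative log-likelihood averaged over voxels.

    ``logits``: class-first reals ``(C, ...)``; ``target``: integer labels of
    the spatial shape.  ``class_weights=None`` computes inverse-prevalence
    weights from the batch (mean-normalized to 1).
    """
    shape = logits.shape if not isinstance(logits, T.Tensor) else logits.data.shape
    c = shape[0]
    target = np.asarray(target)
    if class_weights is None:
        class_weights = inverse_prevalence_weights(target, c)
    class_weights = np.asarray(class_weights, dtype=float)
    onehot = np.moveaxis(np.eye(c)[target.ravel()], -1, 0).reshape(shape)
    wmap = class_weights[target]  # per-voxel weight
    lp = log_softmax(logits, xp=xp)
    return -xp.sum(lp * onehot * wmap) / target.size


def curvature_penalty(k, k_ref: float, xp=np):
    """Log-space quadratic keeping adaptive curvature near its reference."""
    return (xp.log(k) - float(np.log(k_ref))) ** 2


def euclidean_weight_penalty(params, xp=np):
    """Mean of squared entries over the given Euclidean weight arrays."""
    params = list(params)
    if not params:
        return 0.0
    total = None
    n = 0
    for p in params:
        sq = xp.sum(p * p)
        total = sq if total is None else total + sq
        n += p.size if not isinstance(p, T.Tensor) else p.data.size
    return total / n


def combined_loss(ce, curv, idwh, eucl, w: LossWeights):
    """alpha*ce + gamma*curv + delta*idwh + epsilon*eucl."""
    return w.alpha * ce + w.gamma * curv + w.delta * idwh + w.epsilon * eucl
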