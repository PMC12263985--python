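"""Training loop implementing the two-group optimization recipe:

* Euclidean parameters: SGD with momentum 0.9 and polynomial learning-rate
  decay ``lr(t) = lr0 * (1 - t/T)^0.9``;
* hyperbolic parameters (curvature sigma, HMLR plane offsets and scales,
  Mobius bias points): learning rate 0.1, ball points stepped with
  Riemannian SGD (no momentum), capped at ``poincare_max_iters`` updates.

Composite loss = alpha*CE + gamma*curvature + delta*IDWH + epsilon*L2.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .data import PhantomSample, sample_balanced_patches, augment
from .errors import ConfigurationError
from .losses import (
    LossWeights, combined_loss, curvature_penalty, euclidean_weight_penalty,
    hmlr_cross_entropy, idwh_loss, inverse_distance_weights,
    inverse_prevalence_weights, log_softmax,
)
from .manifold import BallPoint, riemannian_sgd_step
from .metrics import confusion_metrics
from .network import (
    HyperbolicUNet3D, ModelConfig, UNet3D, build_hyperbolic_unet, build_stage1_unet,
)

__all__ = ["TrainConfig", "train", "TrainingLog", "SGDOptimizer"]


@dataclass
class TrainConfig:
    epochs: int = 600
    batch_size: int = 2
    euclid_lr: float = 0.02
    euclid_momentum: float = 0.9
    poly_power: float = 0.9
    poincare_lr: float = 0.1
    poincare_max_iters: int = 10_000
    seed: int = 0
    patch_size: int = 24
    patches_per_sample: int = 2
    val_fraction: float = 0.1
    augment: bool = True
    loss: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)
    early_stop_val_dice: float | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        for name in ("euclid_lr", "poincare_lr", "batch_size", "patch_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class TrainingLog:
    entries: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0

    def append(self, **kw):
        self.entries.append(kw)

    def dump(self, path):
        with open(path, "w") as f:
            for e in self.entries:
                f.write(json.dumps(e) + "\n")


class SGDOptimizer:
    """Momentum SGD for Euclidean tensors + Riemannian SGD for ball points."""

    def __init__(self, model, cfg: TrainConfig):
        self.model = model
        self.cfg = cfg
        self.velocity = {n: np.zeros_like(p.data)
                         for n, p in model.params.items()
                         if model.kinds[n] in ("weight", "bias")}
        self.manifold_iters = 0

    def step(self, epoch: int) -> None:
        cfg = self.cfg
        frac = min(epoch / max(cfg.epochs, 1), 1.0)
        lr = cfg.euclid_lr * (1.0 - frac) ** cfg.poly_power
        k = None
        manifold_frozen = self.manifold_iters >= cfg.poincare_max_iters
        for name, p in self.model.params.items():
            if p.grad is None:
                continue
            kind = self.model.kinds[name]
            if kind in ("weight", "bias"):
                v = self.velocity[name]
                v *= cfg.euclid_momentum
                v -= lr * p.grad
                p.data = p.data + v
            elif kind == "hyper_scalar":
                if not manifold_frozen:
                    p.data = p.data - cfg.poincare_lr * p.grad
            elif kind == "manifold":
                if not manifold_frozen:
                    if k is None:
                        k = _current_curvature(self.model)
                    pt = BallPoint(p.data.astype(np.float64), k)
                    new = riemannian_sgd_step(pt, p.grad.astype(np.float64),
                                              cfg.poincare_lr, k)
                    p.data = new.coords.astype(p.data.dtype)
        if not manifold_frozen:
            self.manifold_iters += 1
        self.model.zero_grad()


def _current_curvature(model) -> float:
    if isinstance(model, HyperbolicUNet3D):
        with T.no_grad():
            return float(model.curvature_tensor().data)
    return model.cfg.manifold.curvature


def _stage_input(sample_vol, stage: int) -> np.ndarray:
    if stage == 1:
        return sample_vol.channels["fat"][None]
    return sample_vol.stacked()


def _stage_target(labels: np.ndarray, stage: int) -> np.ndarray:
    return (labels > 0).astype(np.int64) if stage == 1 else labels.astype(np.int64)


def _patch_loss(model, x, y, stage: int, spacing, w: LossWeights, k_ref: float):
    """Composite loss for one patch; returns (loss Tensor, component floats)."""
    logits = model.forward(x)
    c = logits.data.shape[0]
    class_w = inverse_prevalence_weights(y, c)
    ce = hmlr_cross_entropy(logits, y, class_w, xp=T)
    probs = T.exp(log_softmax(logits, xp=T))
    onehot = np.moveaxis(np.eye(c, dtype=np.float32)[y], -1, 0)
    la_mask = (y > 0) if stage == 1 else (y == 1)
    dmap = inverse_distance_weights(la_mask, spacing)
    idwh = idwh_loss(probs, onehot, dmap.weights.astype(np.float32), xp=T)
    eucl = euclidean_weight_penalty(model.euclidean_weights(), xp=T)
    if isinstance(model, HyperbolicUNet3D):
        curv = curvature_penalty(model.curvature_tensor(), k_ref, xp=T)
    else:
        curv = T.Tensor(np.float32(0.0))
    loss = combined_loss(ce, curv, idwh, eucl, w)
    comps = {"ce": float(ce.data), "curv": float(curv.data),
             "idwh": float(idwh.data), "eucl": float(eucl.data),
             "total": float(loss.data)}
    return loss, comps


def _val_dice(model, samples, stage: int) -> float:
    """Mean foreground Dice over full validation volumes."""
    scores = []
    with T.no_grad():
        for s in samples:
            x = _stage_input(s.volume, stage)
            y = _stage_target(s.labels.labels, stage)
            pred = np.argmax(model.forward(x).data, axis=0)
            classes = (1,) if stage == 1 else (1, 2)
            dices = [confusion_metrics(pred, y, c)[0] for c in classes]
            scores.append(float(np.mean(dices)))
    return float(np.mean(scores)) if scores else float("nan")


def train(stage: int, dataset: list, cfg: TrainConfig, log_path=None):
    """Train a stage-1 UNet or stage-2 hyperbolic UNet on phantom samples.

    Returns ``(model, log)`` with the best-validation parameters restored.
    """
    if stage not in (1, 2):
        raise ConfigurationError("stage must be 1 or 2")
    if not dataset:
        raise ConfigurationError("dataset must be nonempty")
    for s in dataset:
        if not isinstance(s, PhantomSample):
            raise ConfigurationError("dataset entries must be PhantomSample")

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(dataset)))
    n_val = max(1, n_val) if len(dataset) >= 2 else 0
    train_set = dataset[:len(dataset) - n_val] if n_val else list(dataset)
    val_set = dataset[len(dataset) - n_val:] if n_val else list(dataset)

    model_cfg = cfg.model
    if stage == 1:
        model = build_stage1_unet(model_cfg, seed=cfg.seed)
    else:
        model = build_hyperbolic_unet(model_cfg, seed=cfg.seed)
    k_ref = model_cfg.manifold.curvature
    opt = SGDOptimizer(model, cfg)
    log = TrainingLog()
    best_state = None

    for epoch in range(cfg.epochs):
        comps_sum: dict = {}
        n_batches = 0
        pending = 0
        for si, sample in enumerate(train_set):
            pseed = int(rng.integers(2 ** 31))
            patches = sample_balanced_patches(sample, cfg.patch_size,
                                              cfg.patches_per_sample, seed=pseed)
            for pi, (pvol, plab) in enumerate(patches):
                x = _stage_input(pvol, stage).astype(np.float32)
                y = _stage_target(plab.labels, stage)
                if cfg.augment:
                    x, y = augment(x, y, seed=int(rng.integers(2 ** 31)))
                    x = x.astype(np.float32)
                    y = y.astype(np.int64)
                loss, comps = _patch_loss(model, x, y, stage,
                                          pvol.spacing, cfg.loss, k_ref)
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {comps}")
                (loss * (1.0 / cfg.batch_size)).backward()
                pending += 1
                for key, val in comps.items():
                    comps_sum[key] = comps_sum.get(key, 0.0) + val
                n_batches += 1
                if pending == cfg.batch_size:
                    opt.step(epoch)
                    pending = 0
        if pending:
            opt.step(epoch)
        val_dice = _val_dice(model, val_set, stage)
        entry = {"epoch": epoch,
                 **{k: v / max(n_batches, 1) for k, v in comps_sum.items()},
                 "val_dice": val_dice,
                 "curvature": _current_curvature(model),
                 "manifold_iters": opt.manifold_iters}
        log.append(**entry)
        if val_dice > log.best_val_dice:
            log.best_val_dice = val_dice
            log.best_epoch = epoch
            best_state = copy.deepcopy(model.state_arrays())
        if (cfg.early_stop_val_dice is not None
                and val_dice >= cfg.early_stop_val_dice):
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    if log_path is not None:
        log.dump(log_path)
    return model, log
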