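"""Two-stage segmentation networks.

Stage 1 is a plain 3-D UNet that localizes the region of interest on the
fat channel.  Stage 2 is a UNet whose encoder blocks run a Euclidean and a
hyperbolic (Poincare-ball) convolution branch in parallel — features are
embedded into the ball with the exponential map at the origin, convolved in
the tangent space, Mobius-shifted by a learned bias point and mapped back —
and whose head classifies each voxel by signed hyperbolic distance to
learnable class planes (hyperbolic multinomial logistic regression).  Ball
curvature is learned through ``k = exp(l_k * sigma) + l_0``.

All feature fields are channel-first ``(C, D, H, W)``; channel vectors of
hyperbolic fields live inside the ball of the current curvature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import tensor as T
from .data import CHANNEL_ORDER, LabelVolume, SegVolume
from .errors import ConfigurationError, InputError
from .manifold import (
    ManifoldParams, _dist_to_plane, _exp_map, _log_map, _mobius_add,
    _norm, _project, _sqnorm,
)

CHECKPOINT_VERSION = 1

__all__ = [
    "ModelConfig", "FeatureField", "UNet3D", "HyperbolicUNet3D",
    "conv_block", "poincare_embed", "mobius_conv", "dual_encoder_block",
    "hmlr_logits", "build_stage1_unet", "build_hyperbolic_unet",
    "crop_to_roi", "uncrop_labels", "two_stage_predict", "CropRecord",
    "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration & feature fields
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    base_channels: int = 8
    depth: int = 3
    num_classes: int = 3
    patch_size: int = 96
    use_hyperbolic_attention: bool = False
    manifold: ManifoldParams = field(default_factory=ManifoldParams)
    in_channels: int = 3

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.patch_size % (2 ** (self.depth - 1)):
            raise ConfigurationError(
                f"patch_size {self.patch_size} not divisible by 2^(depth-1)")

    def to_dict(self):
        d = {k: getattr(self, k) for k in
             ("base_channels", "depth", "num_classes", "patch_size",
              "use_hyperbolic_attention", "in_channels")}
        m = self.manifold
        d["manifold"] = {"sigma": m.sigma, "l_k": m.l_k, "l_0": m.l_0,
                         "eps_ball": m.eps_ball}
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["manifold"] = ManifoldParams(**d.get("manifold", {}))
        return cls(**d)


@dataclass
class FeatureField:
    """A channel-vector field over a 3-D lattice, tagged by its space."""

    grid: object  # Tensor or ndarray, (C, D, H, W)
    space_tag: str = "euclidean"
    curvature: float | None = None

    def __post_init__(self):
        if self.space_tag not in ("euclidean", "hyperbolic"):
            raise ConfigurationError(f"unknown space tag {self.space_tag!r}")
        if self.space_tag == "hyperbolic" and self.curvature is None:
            raise ConfigurationError("hyperbolic fields need a curvature")


def _grid(x):
    return x.grid if isinstance(x, FeatureField) else x


# ---------------------------------------------------------------------------
# layer operations (Tensor-level)
# ---------------------------------------------------------------------------

def _conv_block(x, w, b):
    if _shape(x)[0] != _shape(w)[1]:
        raise ConfigurationError(
            f"conv_block: input has {_shape(x)[0]} channels, weights expect {_shape(w)[1]}")
    return T.relu(T.conv3d(x, w, b))


def _shape(t):
    return t.data.shape if isinstance(t, T.Tensor) else np.asarray(t).shape


def _dtype_of(t):
    return t.data.dtype if isinstance(t, T.Tensor) else np.asarray(t).dtype


def _embed(x, k):
    """Exponential map at the origin, channel-vector-wise, then projection."""
    zero = np.zeros((1, 1, 1, 1), dtype=_dtype_of(x))
    q = _exp_map(zero, x, k, axis=0, xp=T)
    return _project(q, k, 1e-5, axis=0, xp=T)


def _log_origin(q, k):
    zero = np.zeros((1, 1, 1, 1), dtype=_dtype_of(q))
    return _log_map(zero, q, k, axis=0, xp=T)


def _mobius_conv(f, w, bias_point, k):
    """Tangent-space approximation: log at origin -> conv -> exp at origin,
    then Mobius-add the learned bias point."""
    v = _log_origin(f, k)
    v = T.conv3d(v, w)
    q = _embed(v, k)
    c = _shape(bias_point)[0]
    bp = T.reshape(bias_point, (c, 1, 1, 1))
    bp = _project(bp, k, 1e-5, axis=0, xp=T)
    out = _mobius_add(bp, q, k, axis=0, xp=T)
    return _project(out, k, 1e-5, axis=0, xp=T)


def _hyperbolic_attention(f, k):
    """Optional gating: softmax over the 3^3 neighbourhood of negative
    hyperbolic distances, applied to the tangent representation."""
    v = _log_origin(f, k)
    c, d, h, w = _shape(v)
    vp = T.pad(v, ((0, 0), (1, 1), (1, 1), (1, 1)))
    f_pad = T.pad(f, ((0, 0), (1, 1), (1, 1), (1, 1)))
    scores, neighbors = [], []
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                sl = (slice(None), slice(dz, dz + d),
                      slice(dy, dy + h), slice(dx, dx + w))
                nb = f_pad[sl]
                diff = _mobius_add(-1.0 * f, nb, k, axis=0, xp=T)
                dist = _norm(diff, axis=0, xp=T)  # (1, D, H, W)
                scores.append(-1.0 * dist)
                neighbors.append(vp[sl])
    smax = np.max(np.stack([s.data for s in scores]), axis=0)
    exps = [T.exp(s - smax) for s in scores]
    z = exps[0]
    for e in exps[1:]:
        z = z + e
    out = None
    for e, nb in zip(exps, neighbors):
        contrib = (e / z) * nb
        out = contrib if out is None else out + contrib
    return _embed(out, k)


def _hmlr(z, planes, k):
    """Per-voxel per-class logits from signed distances to class planes.

    ``planes``: list of dicts with Tensors ``p`` (offset, shape (C,)),
    ``a`` (normal, (C,)) and ``log_zeta`` (scalar).
    """
    c = _shape(z)[0]
    logits = []
    for pl in planes:
        p = T.reshape(pl["p"], (c, 1, 1, 1))
        p = _project(p, k, 1e-5, axis=0, xp=T)
        a = T.reshape(pl["a"], (c, 1, 1, 1))
        zeta = T.exp(pl["log_zeta"])
        lam_p = 2.0 / (1.0 - k * _sqnorm(p, axis=0, xp=T))
        dist = _dist_to_plane(z, p, a, k, axis=0, xp=T)
        an = _norm(a, axis=0, xp=T)
        logits.append(zeta * lam_p * an * dist)
    return T.concatenate(logits, axis=0)


# ---------------------------------------------------------------------------
# public FeatureField-level operations
# ---------------------------------------------------------------------------

def conv_block(x, weights, bias):
    """ReLU(conv3d(x)) — shape-preserving 3x3x3 convolution block."""
    out = _conv_block(T.as_tensor(_grid(x)), T.as_tensor(weights), T.as_tensor(bias))
    return FeatureField(out, "euclidean")


def poincare_embed(f, m: ManifoldParams) -> FeatureField:
    """Map a Euclidean field into the ball of curvature k(m), channel-wise."""
    k = m.curvature if isinstance(m, ManifoldParams) else float(m)
    out = _embed(T.as_tensor(_grid(f)), k)
    return FeatureField(out, "hyperbolic", curvature=k)


def mobius_conv(f, weights, bias_point, m: ManifoldParams) -> FeatureField:
    """Hyperbolic convolution via the tangent-space approximation."""
    k = m.curvature if isinstance(m, ManifoldParams) else float(m)
    out = _mobius_conv(T.as_tensor(_grid(f)), T.as_tensor(weights),
                       T.as_tensor(bias_point), k)
    return FeatureField(out, "hyperbolic", curvature=k)


def hmlr_logits(z, planes, m: ManifoldParams):
    """Logits (num_classes, D, H, W) from a hyperbolic feature field."""
    k = m.curvature if isinstance(m, ManifoldParams) else float(m)
    if not planes:
        raise ConfigurationError("hmlr_logits needs one plane per class")
    tensor_planes = []
    for pl in planes:
        if isinstance(pl, dict):
            tensor_planes.append({kk: T.as_tensor(vv) for kk, vv in pl.items()})
        else:  # manifold.ClassPlane
            tensor_planes.append({
                "p": T.as_tensor(pl.offset.coords),
                "a": T.as_tensor(pl.normal),
                "log_zeta": T.as_tensor(np.log(pl.zeta)),
            })
    return _hmlr(T.as_tensor(_grid(z)), tensor_planes, k)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _he_conv(rng, cout, cin, ksize=3, dtype=np.float64):
    std = np.sqrt(2.0 / (cin * ksize ** 3))
    return rng.normal(scale=std, size=(cout, cin, ksize, ksize, ksize)).astype(dtype)


class _Model:
    """Parameter registry shared by both networks."""

    def __init__(self):
        self.params: dict[str, T.Tensor] = {}
        self.kinds: dict[str, str] = {}  # weight | bias | manifold | hyper_scalar

    def _add(self, name, array, kind, dtype):
        t = T.parameter(array, dtype=dtype)
        self.params[name] = t
        self.kinds[name] = kind
        return t

    def euclidean_weights(self):
        return [p for n, p in self.params.items() if self.kinds[n] == "weight"]

    def manifold_param_names(self):
        return [n for n, k in self.kinds.items() if k == "manifold"]

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def state_arrays(self):
        return {n: p.data for n, p in self.params.items()}

    def load_state_arrays(self, arrays):
        for n, p in self.params.items():
            if n not in arrays:
                raise InputError(f"checkpoint missing parameter {n!r}")
            if arrays[n].shape != p.data.shape:
                raise InputError(f"checkpoint parameter {n!r} has shape "
                                 f"{arrays[n].shape}, expected {p.data.shape}")
            p.data = arrays[n].astype(p.data.dtype)


class UNet3D(_Model):
    """Stage-1 ROI localizer: plain encoder/decoder, fat channel in,
    2-class (foreground vs background) logits out."""

    kind = "unet3d"

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.widths = w
        cin = cfg.in_channels
        for i in range(cfg.depth - 1):
            self._add(f"enc{i}.convA.w", _he_conv(rng, w[i], cin), "weight", dtype)
            self._add(f"enc{i}.convA.b", np.zeros(w[i]), "bias", dtype)
            self._add(f"enc{i}.convB.w", _he_conv(rng, w[i], w[i]), "weight", dtype)
            self._add(f"enc{i}.convB.b", np.zeros(w[i]), "bias", dtype)
            cin = w[i]
        self._add("bott.convA.w", _he_conv(rng, w[-1], cin), "weight", dtype)
        self._add("bott.convA.b", np.zeros(w[-1]), "bias", dtype)
        self._add("bott.convB.w", _he_conv(rng, w[-1], w[-1]), "weight", dtype)
        self._add("bott.convB.b", np.zeros(w[-1]), "bias", dtype)
        prev = w[-1]
        for i in reversed(range(cfg.depth - 1)):
            self._add(f"dec{i}.up.w",
                      rng.normal(scale=np.sqrt(2.0 / prev),
                                 size=(prev, w[i], 2, 2, 2)), "weight", dtype)
            self._add(f"dec{i}.up.b", np.zeros(w[i]), "bias", dtype)
            self._add(f"dec{i}.conv.w", _he_conv(rng, w[i], 2 * w[i]), "weight", dtype)
            self._add(f"dec{i}.conv.b", np.zeros(w[i]), "bias", dtype)
            prev = w[i]
        self._add("head.w", _he_conv(rng, self.out_classes, w[0], ksize=1),
                  "weight", dtype)
        self._add("head.b", np.zeros(self.out_classes), "bias", dtype)

    @property
    def out_classes(self):
        return 2

    def forward(self, x) -> T.Tensor:
        x = T.as_tensor(np.asarray(_grid(x), dtype=self.dtype))
        self._check_spatial(x)
        p = self.params
        skips = []
        for i in range(self.cfg.depth - 1):
            x = _conv_block(x, p[f"enc{i}.convA.w"], p[f"enc{i}.convA.b"])
            x = _conv_block(x, p[f"enc{i}.convB.w"], p[f"enc{i}.convB.b"])
            skips.append(x)
            x = T.maxpool3d_2x(x)
        x = _conv_block(x, p["bott.convA.w"], p["bott.convA.b"])
        x = _conv_block(x, p["bott.convB.w"], p["bott.convB.b"])
        for i in reversed(range(self.cfg.depth - 1)):
            x = T.conv_transpose3d_2x(x, p[f"dec{i}.up.w"], p[f"dec{i}.up.b"])
            x = T.concatenate([x, skips[i]], axis=0)
            x = _conv_block(x, p[f"dec{i}.conv.w"], p[f"dec{i}.conv.b"])
        return T.conv3d(x, p["head.w"], p["head.b"], padding=0)

    def _check_spatial(self, x):
        m = 2 ** (self.cfg.depth - 1)
        if any(s % m for s in x.data.shape[1:]):
            raise ConfigurationError(
                f"spatial shape {x.data.shape[1:]} not divisible by {m}")


class HyperbolicUNet3D(_Model):
    """Stage-2 model: dual Euclidean/hyperbolic encoder, Euclidean decoder,
    hyperbolic multinomial logistic regression head, learned curvature."""

    kind = "hyperbolic_unet3d"

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.widths = w
        self._add("sigma", cfg.manifold.sigma, "hyper_scalar", dtype)
        cin = cfg.in_channels
        for i in range(cfg.depth - 1):
            self._add(f"enc{i}.stem.w", _he_conv(rng, w[i], cin), "weight", dtype)
            self._add(f"enc{i}.stem.b", np.zeros(w[i]), "bias", dtype)
            self._add(f"enc{i}.euclid.w", _he_conv(rng, w[i], w[i]), "weight", dtype)
            self._add(f"enc{i}.euclid.b", np.zeros(w[i]), "bias", dtype)
            self._add(f"enc{i}.hyper.w", _he_conv(rng, w[i], w[i]), "weight", dtype)
            self._add(f"enc{i}.hyper.bias_point", np.zeros(w[i]), "manifold", dtype)
            cin = 2 * w[i]
        bott = 2 * w[cfg.depth - 2]
        self._add("bott.convA.w", _he_conv(rng, bott, cin), "weight", dtype)
        self._add("bott.convA.b", np.zeros(bott), "bias", dtype)
        self._add("bott.convB.w", _he_conv(rng, bott, bott), "weight", dtype)
        self._add("bott.convB.b", np.zeros(bott), "bias", dtype)
        prev = bott
        for i in reversed(range(cfg.depth - 1)):
            self._add(f"dec{i}.up.w",
                      rng.normal(scale=np.sqrt(2.0 / prev),
                                 size=(prev, w[i], 2, 2, 2)), "weight", dtype)
            self._add(f"dec{i}.up.b", np.zeros(w[i]), "bias", dtype)
            self._add(f"dec{i}.conv.w", _he_conv(rng, w[i], 3 * w[i]), "weight", dtype)
            self._add(f"dec{i}.conv.b", np.zeros(w[i]), "bias", dtype)
            prev = w[i]
        feat = w[0]
        for c in range(cfg.num_classes):
            self._add(f"head.plane{c}.p", np.zeros(feat), "manifold", dtype)
            self._add(f"head.plane{c}.a",
                      rng.normal(scale=1.0 / np.sqrt(feat), size=feat),
                      "weight", dtype)
            self._add(f"head.plane{c}.log_zeta", 0.0, "hyper_scalar", dtype)

    def curvature_tensor(self) -> T.Tensor:
        m = self.cfg.manifold
        return T.exp(self.params["sigma"] * m.l_k) + m.l_0

    def encoder_block(self, x, i, k):
        p = self.params
        stem = _conv_block(x, p[f"enc{i}.stem.w"], p[f"enc{i}.stem.b"])
        f_e = _conv_block(stem, p[f"enc{i}.euclid.w"], p[f"enc{i}.euclid.b"])
        f_h = _embed(stem, k)
        if self.cfg.use_hyperbolic_attention:
            f_h = _hyperbolic_attention(f_h, k)
        f_h = _mobius_conv(f_h, p[f"enc{i}.hyper.w"],
                           p[f"enc{i}.hyper.bias_point"], k)
        cat = T.concatenate([f_e, _log_origin(f_h, k)], axis=0)
        return cat  # pooled by the caller; `cat` is also the skip tensor

    def forward(self, x) -> T.Tensor:
        x = T.as_tensor(np.asarray(_grid(x), dtype=self.dtype))
        m = 2 ** (self.cfg.depth - 1)
        if any(s % m for s in x.data.shape[1:]):
            raise ConfigurationError(
                f"spatial shape {x.data.shape[1:]} not divisible by {m}")
        p = self.params
        k = self.curvature_tensor()
        skips = []
        for i in range(self.cfg.depth - 1):
            cat = self.encoder_block(x, i, k)
            skips.append(cat)
            x = T.maxpool3d_2x(cat)
        x = _conv_block(x, p["bott.convA.w"], p["bott.convA.b"])
        x = _conv_block(x, p["bott.convB.w"], p["bott.convB.b"])
        for i in reversed(range(self.cfg.depth - 1)):
            x = T.conv_transpose3d_2x(x, p[f"dec{i}.up.w"], p[f"dec{i}.up.b"])
            x = T.concatenate([x, skips[i]], axis=0)
            x = _conv_block(x, p[f"dec{i}.conv.w"], p[f"dec{i}.conv.b"])
        z = _embed(x, k)
        planes = [{"p": p[f"head.plane{c}.p"], "a": p[f"head.plane{c}.a"],
                   "log_zeta": p[f"head.plane{c}.log_zeta"]}
                  for c in range(self.cfg.num_classes)]
        return _hmlr(z, planes, k)


def build_stage1_unet(cfg: ModelConfig, seed: int = 0) -> UNet3D:
    """Plain 3-D UNet over the fat channel -> 2-class foreground map."""
    return UNet3D(replace(cfg, in_channels=1), seed=seed)


def build_hyperbolic_unet(cfg: ModelConfig, seed: int = 0) -> HyperbolicUNet3D:
    """Dual-branch hyperbolic UNet over water+fat+fat_fraction -> 3 classes."""
    return HyperbolicUNet3D(replace(cfg, in_channels=3), seed=seed)


def dual_encoder_block(x, cfg: ModelConfig, seed: int = 0):
    """Stand-alone dual encoder block: conv -> parallel Euclidean/hyperbolic
    branches -> concat -> 2x MaxPool.  Halves spatial dims, output channels
    are twice the branch width."""
    model = HyperbolicUNet3D(cfg, seed=seed)
    g = T.as_tensor(np.asarray(_grid(x), dtype=model.dtype))
    if any(s % 2 for s in g.data.shape[1:]):
        raise ConfigurationError(f"odd spatial dims {g.data.shape[1:]}")
    cat = model.encoder_block(g, 0, model.curvature_tensor())
    return FeatureField(T.maxpool3d_2x(cat), "euclidean")


# ---------------------------------------------------------------------------
# ROI cropping & two-stage inference
# ---------------------------------------------------------------------------

@dataclass
class CropRecord:
    slices: tuple
    original_shape: tuple
    pad: tuple  # per-axis (before, after) zero padding applied after cropping


def crop_to_roi(v: SegVolume, mask, margin: int = 8,
                multiple: int = 4) -> tuple:
    """Crop to the bounding box of ``mask`` (+``margin`` voxels), padded up to
    a multiple of ``multiple``; an empty mask falls back to the full volume."""
    mask_arr = mask.labels if isinstance(mask, LabelVolume) else np.asarray(mask)
    if mask_arr.shape != v.shape:
        raise InputError(f"mask shape {mask_arr.shape} != volume shape {v.shape}")
    shape = v.shape
    nz = np.argwhere(mask_arr != 0)
    if len(nz) == 0:
        lo = [0, 0, 0]
        hi = list(shape)
    else:
        lo = [max(int(nz[:, ax].min()) - margin, 0) for ax in range(3)]
        hi = [min(int(nz[:, ax].max()) + margin + 1, shape[ax]) for ax in range(3)]
    pads = []
    for ax in range(3):
        size = hi[ax] - lo[ax]
        target = int(np.ceil(size / multiple) * multiple)
        extra = target - size
        # grow inside the volume first, pad with zeros only if it cannot fit
        grow_hi = min(extra, shape[ax] - hi[ax])
        hi[ax] += grow_hi
        extra -= grow_hi
        grow_lo = min(extra, lo[ax])
        lo[ax] -= grow_lo
        extra -= grow_lo
        pads.append((0, extra))
    slices = tuple(slice(l, h) for l, h in zip(lo, hi))
    channels = {}
    for name, ch in v.channels.items():
        c = ch[slices]
        if any(p != (0, 0) for p in pads):
            c = np.pad(c, pads)
        channels[name] = c
    record = CropRecord(slices, shape, tuple(pads))
    return SegVolume(channels, v.spacing, affine=v.affine), record


def uncrop_labels(labels: np.ndarray, record: CropRecord) -> np.ndarray:
    """Re-embed cropped predictions into the original grid (background outside)."""
    inner = labels
    for ax, (before, after) in enumerate(record.pad):
        idx = [slice(None)] * labels.ndim
        idx[ax] = slice(before, inner.shape[ax] - after)
        inner = inner[tuple(idx)]
    full = np.zeros(record.original_shape, dtype=labels.dtype)
    full[record.slices] = inner
    return full


def two_stage_predict(v: SegVolume, stage1, stage2, margin: int = 8,
                      oracle_mask=None) -> LabelVolume:
    """Stage-1 foreground -> ROI crop -> stage-2 3-class segmentation,
    re-embedded into the full grid.

    ``oracle_mask`` replaces the stage-1 prediction (used for integration
    tests and for --no-crop style workflows with a precomputed ROI).
    """
    for name in CHANNEL_ORDER:
        if name not in v.channels:
            raise InputError(f"missing channel {name!r}")
    multiple = 2 ** (stage2.cfg.depth - 1)
    with T.no_grad():
        if oracle_mask is None:
            fat = v.channels["fat"][None]
            mask = np.argmax(stage1.forward(fat).data, axis=0).astype(np.int16)
        else:
            mask = np.asarray(oracle_mask).astype(np.int16)
        cropped, record = crop_to_roi(v, mask, margin=margin, multiple=multiple)
        logits = stage2.forward(cropped.stacked())
        pred = np.argmax(logits.data, axis=0).astype(np.int16)
    full = uncrop_labels(pred, record)
    return LabelVolume(full, v.spacing, affine=v.affine)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path) -> None:
    """Single-file .npz archive: parameters + JSON config + version field."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": model.kind,
        "config": model.cfg.to_dict(),
        "dtype": np.dtype(model.dtype).name,
        "sigma": float(model.params["sigma"].data) if "sigma" in model.params else None,
    }
    arrays = {f"param:{n}": a for n, a in model.state_arrays().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    with np.load(str(path), allow_pickle=False) as z:
        if "__meta__" not in z:
            raise InputError(f"{path} is not a model checkpoint")
        meta = json.loads(str(z["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise InputError(
                f"checkpoint version {meta.get('version')} != {CHECKPOINT_VERSION}")
        cfg = ModelConfig.from_dict(meta["config"])
        dtype = np.dtype(meta["dtype"])
        if meta["kind"] == UNet3D.kind:
            model = UNet3D(cfg, dtype=dtype)
        elif meta["kind"] == HyperbolicUNet3D.kind:
            model = HyperbolicUNet3D(cfg, dtype=dtype)
        else:
            raise InputError(f"unknown model kind {meta['kind']!r}")
        arrays = {n[len("param:"):]: z[n] for n in z.files if n.startswith("param:")}
    model.load_state_arrays(arrays)
    return model
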