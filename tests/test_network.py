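"""Network module: layer contracts, shape/gradient invariants, ROI cropping,
two-stage inference and checkpoints."""

import numpy as np
import pytest

from hyperseg import tensor as T
from hyperseg.data import LabelVolume, PhantomConfig, SegVolume, generate_phantom
from hyperseg.errors import ConfigurationError, InputError
from hyperseg.manifold import ManifoldParams
from hyperseg.network import (
    CropRecord, FeatureField, HyperbolicUNet3D, ModelConfig, UNet3D,
    build_hyperbolic_unet, build_stage1_unet, conv_block, crop_to_roi,
    dual_encoder_block, hmlr_logits, load_checkpoint, mobius_conv,
    poincare_embed, save_checkpoint, two_stage_predict, uncrop_labels,
)

RNG = np.random.default_rng(0)


def small_cfg(**kw):
    kw.setdefault("base_channels", 4)
    kw.setdefault("depth", 2)
    kw.setdefault("patch_size", 8)
    return ModelConfig(**kw)


# ---------------------------------------------------------------------------
# conv block
# ---------------------------------------------------------------------------

def test_conv_block_constant_and_shape():
    x = RNG.normal(size=(2, 5, 5, 5))
    w = np.zeros((3, 2, 3, 3, 3))
    b = np.array([0.5, 0.0, 1.5])
    out = conv_block(x, w, b).grid
    assert out.shape == (3, 5, 5, 5)
    for c, v in enumerate(b):
        np.testing.assert_allclose(out.data[c], v)


def test_conv_block_impulse_identity_kernel():
    x = np.zeros((1, 5, 5, 5))
    x[0, 2, 2, 2] = 3.0
    w = np.zeros((1, 1, 3, 3, 3))
    w[0, 0, 1, 1, 1] = 1.0
    out = conv_block(x, w, np.zeros(1)).grid
    np.testing.assert_allclose(out.data, x)


def test_conv_block_channel_mismatch():
    with pytest.raises(ConfigurationError):
        conv_block(np.zeros((2, 4, 4, 4)), np.zeros((3, 5, 3, 3, 3)), np.zeros(3))


# ---------------------------------------------------------------------------
# hyperbolic layers
# ---------------------------------------------------------------------------

def test_poincare_embed_invariants():
    m = ManifoldParams(sigma=0.0)
    k = m.curvature
    f = RNG.normal(size=(4, 6, 6, 6)) * 2.0
    out = poincare_embed(f, m)
    assert out.space_tag == "hyperbolic"
    sq = (np.asarray(out.grid.data) ** 2).sum(axis=0)
    assert np.all(k * sq < 1.0)
    # zero features map to the origin
    out0 = poincare_embed(np.zeros((4, 3, 3, 3)), m)
    np.testing.assert_allclose(out0.grid.data, 0.0, atol=1e-12)


def test_poincare_embed_euclidean_limit():
    m = ManifoldParams(sigma=np.log(1e-6), l_0=1e-9)  # k ~ 1e-6
    f = RNG.normal(size=(3, 4, 4, 4))
    out = poincare_embed(f, m)
    np.testing.assert_allclose(out.grid.data, f, atol=1e-4)


def test_mobius_conv_zero_weights_zero_bias():
    m = ManifoldParams(sigma=0.0)
    f = poincare_embed(RNG.normal(size=(3, 4, 4, 4)), m)
    out = mobius_conv(f, np.zeros((3, 3, 3, 3, 3)), np.zeros(3), m)
    np.testing.assert_allclose(out.grid.data, 0.0, atol=1e-12)
    sq = (np.asarray(out.grid.data) ** 2).sum(axis=0)
    assert np.all(m.curvature * sq < 1.0)


def test_mobius_conv_euclidean_limit_matches_plain_conv():
    m = ManifoldParams(sigma=np.log(1e-6), l_0=1e-9)
    x = RNG.normal(size=(2, 5, 5, 5)) * 0.3
    w = RNG.normal(size=(2, 2, 3, 3, 3)) * 0.2
    f = poincare_embed(x, m)
    out = mobius_conv(f, w, np.zeros(2), m)
    ref = T.conv3d(T.Tensor(x), T.Tensor(w)).data
    np.testing.assert_allclose(out.grid.data, ref, atol=1e-4)


# ---------------------------------------------------------------------------
# dual encoder block
# ---------------------------------------------------------------------------

def test_dual_encoder_block_contracts():
    cfg = small_cfg(in_channels=3)
    x = RNG.normal(size=(3, 8, 8, 8)).astype(np.float32)
    out = dual_encoder_block(x, cfg, seed=1)
    assert out.grid.data.shape == (2 * cfg.base_channels, 4, 4, 4)
    with pytest.raises(ConfigurationError):
        dual_encoder_block(RNG.normal(size=(3, 7, 7, 7)).astype(np.float32), cfg)


def test_dual_encoder_hyper_branch_zeroed_equals_plain_conv_pool():
    cfg = small_cfg(in_channels=3)
    model = HyperbolicUNet3D(cfg, seed=2)
    model.params["enc0.hyper.w"].data[:] = 0.0
    model.params["enc0.hyper.bias_point"].data[:] = 0.0
    x = T.as_tensor(RNG.normal(size=(3, 8, 8, 8)).astype(np.float32))
    cat = model.encoder_block(x, 0, model.curvature_tensor())
    pooled = T.maxpool3d_2x(cat)
    w = cfg.base_channels
    # hyperbolic half is exactly zero
    np.testing.assert_allclose(pooled.data[w:], 0.0, atol=1e-7)
    # Euclidean half equals conv(stem) + pool
    from hyperseg.network import _conv_block
    stem = _conv_block(x, model.params["enc0.stem.w"], model.params["enc0.stem.b"])
    fe = _conv_block(stem, model.params["enc0.euclid.w"], model.params["enc0.euclid.b"])
    np.testing.assert_allclose(pooled.data[:w], T.maxpool3d_2x(fe).data, atol=1e-7)


# ---------------------------------------------------------------------------
# HMLR head
# ---------------------------------------------------------------------------

def _random_planes(c, n, scale=0.5):
    rng = np.random.default_rng(5)
    return [{"p": rng.normal(size=c) * 0.1, "a": rng.normal(size=c) * scale,
             "log_zeta": np.array(0.0)} for _ in range(n)]


def test_hmlr_posteriors_sum_to_one_and_symmetry():
    m = ManifoldParams(sigma=0.0)
    z = poincare_embed(RNG.normal(size=(4, 4, 4, 4)), m)
    planes = _random_planes(4, 3)
    logits = hmlr_logits(z, planes, m).data
    probs = np.exp(logits) / np.exp(logits).sum(0, keepdims=True)
    np.testing.assert_allclose(probs.sum(0), 1.0, atol=1e-6)
    # mirrored planes (a, -a, same p): posteriors 0.5/0.5 where z = p
    p = np.zeros(4)
    a = np.ones(4)
    mirrored = [{"p": p, "a": a, "log_zeta": np.array(0.0)},
                {"p": p, "a": -a, "log_zeta": np.array(0.0)}]
    z0 = FeatureField(np.zeros((4, 1, 1, 1)), "hyperbolic", m.curvature)
    lg = hmlr_logits(z0, mirrored, m).data
    np.testing.assert_allclose(lg, 0.0, atol=1e-9)


def test_hmlr_missing_planes():
    m = ManifoldParams()
    with pytest.raises(ConfigurationError):
        hmlr_logits(FeatureField(np.zeros((2, 1, 1, 1)), "hyperbolic", 1.0), [], m)


def test_hmlr_euclidean_limit_ranks_like_linear_classifier():
    m = ManifoldParams(sigma=np.log(1e-6), l_0=1e-9)
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(3, 100, 1, 1))  # 100 "voxels", 3 channels
    planes = _random_planes(3, 2)
    z = poincare_embed(pts, m)
    logits = hmlr_logits(z, planes, m).data.reshape(2, -1)
    for ci, pl in enumerate(planes):
        lin = (np.moveaxis(pts, 0, -1).reshape(-1, 3) - pl["p"]) @ pl["a"]
        assert np.array_equal(np.argsort(logits[ci]), np.argsort(lin))


# ---------------------------------------------------------------------------
# whole models
# ---------------------------------------------------------------------------

def test_stage1_unet_shapes_and_constant_input():
    model = build_stage1_unet(small_cfg(in_channels=1), seed=0)
    x = RNG.normal(size=(1, 8, 8, 8)).astype(np.float32)
    out = model.forward(x)
    assert out.data.shape == (2, 8, 8, 8)
    # all-zero input matches the zero padding, so the response is spatially
    # constant everywhere (translation invariance of the conv net)
    out = model.forward(np.zeros((1, 8, 8, 8), np.float32)).data
    flat = out.reshape(2, -1)
    np.testing.assert_allclose(flat - flat[:, :1], 0.0, atol=1e-6)


def test_stage1_unet_parameter_count_formula():
    cfg = small_cfg(base_channels=4, depth=2, in_channels=1)
    model = build_stage1_unet(cfg, seed=0)
    count = sum(p.data.size for p in model.params.values())
    # hand count, depth 2, base 4, 1 input channel:
    # enc0: convA 1->4 (4*1*27+4), convB 4->4 (4*4*27+4)
    # bottleneck: convA 4->8 (8*4*27+8), convB 8->8 (8*8*27+8)
    # dec0: up 8->4 (8*4*8+4), conv 8->4 (4*8*27+4), head 4->2 (2*4*1+2)
    expected = ((4 * 27 + 4) + (16 * 27 + 4)
                + (32 * 27 + 8) + (64 * 27 + 8)
                + (8 * 4 * 8 + 4) + (4 * 8 * 27 + 4) + (2 * 4 + 2))
    assert count == expected


def test_hyperbolic_unet_forward_backward_finite_nonzero():
    model = build_hyperbolic_unet(ModelConfig(base_channels=4, depth=3,
                                       patch_size=16), seed=0)
    x = RNG.normal(size=(3, 16, 16, 16)).astype(np.float32)
    out = model.forward(x)
    assert out.data.shape == (3, 16, 16, 16)
    T.sum(out * RNG.normal(size=out.data.shape)).backward()
    for name, p in model.params.items():
        assert p.grad is not None and np.all(np.isfinite(p.grad)), name
    assert np.any(model.params["sigma"].grad != 0)
    for c in range(3):
        assert np.any(model.params[f"head.plane{c}.a"].grad != 0)
        assert np.any(model.params[f"head.plane{c}.p"].grad != 0)


def test_forward_deterministic():
    model = build_hyperbolic_unet(small_cfg(in_channels=3), seed=3)
    x = RNG.normal(size=(3, 8, 8, 8)).astype(np.float32)
    a = model.forward(x).data
    b = model.forward(x).data
    np.testing.assert_array_equal(a, b)


def test_hyperbolic_attention_flag_runs():
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8,
                      use_hyperbolic_attention=True, in_channels=3)
    model = build_hyperbolic_unet(cfg, seed=0)
    x = RNG.normal(size=(3, 8, 8, 8)).astype(np.float32)
    out = model.forward(x)
    assert out.data.shape == (3, 8, 8, 8)
    T.sum(out).backward()
    assert np.all(np.isfinite(model.params["sigma"].grad))


# ---------------------------------------------------------------------------
# cropping & two-stage inference
# ---------------------------------------------------------------------------

def _toy_volume(shape=(20, 20, 20)):
    rng = np.random.default_rng(4)
    w = rng.uniform(size=shape)
    f = rng.uniform(size=shape)
    ff = np.clip(f / (f + w + 1e-8), 0, 1)
    return SegVolume({"water": w, "fat": f, "fat_fraction": ff}, (1.0, 1.0, 1.0))


def test_crop_to_roi_empty_mask_full_volume():
    v = _toy_volume()
    cropped, rec = crop_to_roi(v, np.zeros(v.shape, dtype=int), margin=4, multiple=4)
    assert cropped.shape == v.shape
    np.testing.assert_array_equal(cropped.channels["fat"], v.channels["fat"])


def test_crop_to_roi_single_voxel_margin4():
    v = _toy_volume((21, 21, 21))
    mask = np.zeros(v.shape, dtype=int)
    mask[10, 10, 10] = 1
    cropped, rec = crop_to_roi(v, mask, margin=4, multiple=1)
    assert cropped.shape == (9, 9, 9)  # brute-force bounding box 9^3


def test_crop_respects_multiple_and_roundtrip():
    v = _toy_volume()
    mask = np.zeros(v.shape, dtype=int)
    mask[3:8, 5:9, 2:4] = 1
    cropped, rec = crop_to_roi(v, mask, margin=2, multiple=4)
    assert all(s % 4 == 0 for s in cropped.shape)
    # uncrop puts values back at the exact original coordinates
    lab = np.zeros(cropped.shape, dtype=np.int16)
    lab[:] = 7 % 3  # arbitrary constant label 1
    full = uncrop_labels(lab, rec)
    assert full.shape == v.shape
    assert np.all(full[rec.slices] == 1)
    outside = np.ones(v.shape, dtype=bool)
    outside[rec.slices] = False
    assert np.all(full[outside] == 0)


def test_crop_margin_monotonicity():
    v = _toy_volume()
    mask = np.zeros(v.shape, dtype=int)
    mask[6:10, 6:10, 6:10] = 1
    prev_kept = -1
    for margin in (0, 2, 4, 8):
        cropped, rec = crop_to_roi(v, mask, margin=margin, multiple=1)
        inner = np.zeros(v.shape, dtype=int)
        inner[rec.slices] = 1
        kept = int((inner & mask.astype(bool)).sum())
        assert kept == mask.sum()  # never loses foreground
        assert kept >= prev_kept
        prev_kept = kept


def test_crop_shape_mismatch():
    v = _toy_volume()
    with pytest.raises(InputError):
        crop_to_roi(v, np.zeros((4, 4, 4)), margin=1)


def test_two_stage_predict_contracts():
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8, in_channels=3)
    stage1 = build_stage1_unet(cfg, seed=0)
    stage2 = build_hyperbolic_unet(cfg, seed=1)
    v = _toy_volume((12, 12, 12))
    out = two_stage_predict(v, stage1, stage2, margin=2)
    assert out.shape == v.shape
    assert out.spacing == v.spacing
    assert set(np.unique(out.labels)) <= {0, 1, 2}
    # deterministic
    out2 = two_stage_predict(v, stage1, stage2, margin=2)
    np.testing.assert_array_equal(out.labels, out2.labels)


def test_two_stage_with_oracle_mask_matches_stage2_on_true_roi():
    phantom = generate_phantom(PhantomConfig(shape=(32, 32, 32),
                                             la_radii=(10.0, 9.0, 12.0), seed=3))
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8, in_channels=3)
    stage2 = build_hyperbolic_unet(cfg, seed=1)
    oracle = (phantom.labels.labels > 0).astype(np.int16)
    out = two_stage_predict(phantom.volume, None, stage2, margin=4,
                            oracle_mask=oracle)
    cropped, rec = crop_to_roi(phantom.volume, oracle, margin=4, multiple=2)
    with T.no_grad():
        direct = np.argmax(stage2.forward(cropped.stacked()).data, axis=0)
    expected = uncrop_labels(direct.astype(np.int16), rec)
    np.testing.assert_array_equal(out.labels, expected)
    outside = np.ones(phantom.volume.shape, dtype=bool)
    outside[rec.slices] = False
    assert np.all(out.labels[outside] == 0)


def test_missing_channel_rejected():
    v = _toy_volume((8, 8, 8))
    del v.channels["fat_fraction"]
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8, in_channels=3)
    with pytest.raises(InputError):
        two_stage_predict(v, build_stage1_unet(cfg), build_hyperbolic_unet(cfg))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8, in_channels=3)
    model = build_hyperbolic_unet(cfg, seed=6)
    model.params["sigma"].data = np.asarray(0.3, dtype=np.float32)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert isinstance(loaded, HyperbolicUNet3D)
    for n, p in model.params.items():
        np.testing.assert_array_equal(p.data, loaded.params[n].data)
    x = RNG.normal(size=(3, 8, 8, 8)).astype(np.float32)
    np.testing.assert_array_equal(model.forward(x).data, loaded.forward(x).data)


def test_checkpoint_version_mismatch(tmp_path):
    import json
    cfg = ModelConfig(base_channels=2, depth=2, patch_size=8, in_channels=1)
    model = build_stage1_unet(cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    with np.load(path) as z:
        arrays = {n: z[n] for n in z.files}
    meta = json.loads(str(arrays["__meta__"]))
    meta["version"] = 99
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)
    with pytest.raises(InputError):
        load_checkpoint(path)


def test_model_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(depth=3, patch_size=30)  # not divisible by 4
    with pytest.raises(ConfigurationError):
        UNet3D(small_cfg(in_channels=1)).forward(np.zeros((1, 7, 7, 7), np.float32))
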