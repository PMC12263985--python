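# hyperseg

A hyperbolic 3-D UNet toolkit for multi-label segmentation of the left
atrium (LA) and the epicardial adipose tissue (EAT) around it from
Dixon-style water / fat / fat-fraction volumes.

The package implements:

* **`hyperseg.manifold`** — curvature-parametrized Poincaré-ball geometry:
  Möbius addition and scalar multiplication, exponential/logarithmic maps,
  signed distance to class planes, projection, and a Riemannian SGD step.
  Curvature is learnable through `k = exp(l_k · σ) + l_0`.
* **`hyperseg.tensor`** — a minimal reverse-mode autodiff engine over numpy
  (the runtime environment ships no deep-learning framework); supports 3-D
  convolution, transposed convolution, max pooling, upsampling and the
  elementwise transcendentals the geometry needs.
* **`hyperseg.network`** — the two-stage pipeline: a plain 3-D UNet that
  localizes a region of interest on the fat channel (stage 1), and a
  dual-branch UNet (stage 2) whose encoder runs Euclidean and hyperbolic
  convolutions in parallel and whose head classifies voxels by signed
  hyperbolic distance to learnable class planes (hyperbolic multinomial
  logistic regression). Includes ROI cropping, re-embedding, checkpoints.
* **`hyperseg.losses`** — inverse-distance-weighted Dice loss (weights
  `1/(1+d)` from the distance in mm to the LA boundary), weighted
  cross-entropy with inverse-prevalence class weights, curvature and
  L2 regularizers, and the composite loss
  `α·CE + γ·curvature + δ·IDWH + ε·L2` with defaults (0.5, 0.2, 0.5, 0.2).
* **`hyperseg.groundtruth`** — semi-automatic EAT reference labels:
  per-volume fat-fraction normalization, strict `> 0.4` thresholding, and
  intersection with a supplied fat ROI.
* **`hyperseg.data`** — a synthetic Dixon phantom simulator (ellipsoidal
  blood pool, thin wall, patchy high-fat rind, distractor fat, noise),
  NIfTI I/O, balanced patch sampling and augmentation — the whole pipeline
  is testable without clinical data.
* **`hyperseg.metrics`** — Dice/IoU/precision/recall/F1, Hausdorff and
  average symmetric surface distance (mm), volumes in mL, Pearson
  correlation, Bland–Altman statistics.

## CLI

```bash
hyperseg simulate --n 8 --seed 1 --shape 48 --out data/          # phantoms + manifest
hyperseg train --stage 1 --data data/ --config config.yaml --out run1/
hyperseg train --stage 2 --data data/ --config config.yaml --out run2/
hyperseg predict --stage1 run1/stage1.npz --stage2 run2/stage2.npz \
    --input data/sample_007_volume.nii.gz --out pred.nii.gz
hyperseg evaluate --pred pred.nii.gz --truth data/sample_007_labels.nii.gz \
    --out metrics
hyperseg make-gt --fat-fraction ff.nii.gz --roi roi.nii.gz --out eat.nii.gz \
    --threshold 0.4
```

The YAML config has sections `model`, `loss`, `train`, `data`; CLI flags
override file values, and every command logs its effective configuration and
seed next to its outputs. Training uses momentum-SGD with polynomial decay
(power 0.9) for Euclidean parameters and Riemannian SGD (lr 0.1, capped at
10,000 updates) for ball-point parameters, per-epoch validation Dice and
best-checkpoint retention.

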