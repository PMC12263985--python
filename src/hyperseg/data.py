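"""Synthetic Dixon-style phantom simulator, NIfTI I/O, balanced patch
sampling and augmentation.

The phantom emulates the structure of a water/fat separated cardiac
acquisition: an ellipsoidal blood pool (water-dominant) with a thin wall,
a patchy high-fat rind adjacent to the wall (the minority EAT class),
distractor fat blobs far from the chamber, smooth background tissue,
additive Gaussian noise, and a fat-fraction channel recomputed as
``fat / (fat + water)``.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError

CHANNEL_ORDER = ("water", "fat", "fat_fraction")

# water/fat signal pairs per tissue; EAT fat fraction 0.9/(0.9+0.15) = 0.857
# sits safely above the 0.4 reference threshold
TISSUE_SIGNALS = {
    "blood": (1.0, 0.05),
    "wall": (0.8, 0.1),
    "eat": (0.15, 0.9),
    "distractor": (0.1, 0.95),
    "background": (0.4, 0.2),
}

__all__ = [
    "SegVolume", "LabelVolume", "PhantomConfig", "PhantomSample",
    "generate_phantom", "generate_dataset", "sample_balanced_patches",
    "augment", "apply_augmentation",
    "read_volume", "write_volume", "read_labels", "write_labels",
    "CHANNEL_ORDER",
]


# ---------------------------------------------------------------------------
# spacing-aware volumes
# ---------------------------------------------------------------------------

@dataclass
class SegVolume:
    """Named co-registered channels (water, fat, fat_fraction) + voxel spacing (mm)."""

    channels: dict
    spacing: tuple
    affine: np.ndarray | None = None

    def __post_init__(self):
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise InputError(f"channel shapes differ: {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be strictly positive, got {self.spacing}")
        ff = self.channels.get("fat_fraction")
        if ff is not None and ff.size and (ff.min() < 0 or ff.max() > 1):
            raise InputError("fat_fraction must lie in [0, 1]")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def stacked(self) -> np.ndarray:
        """Channel-first array in the documented order."""
        return np.stack([self.channels[name] for name in CHANNEL_ORDER])


@dataclass
class LabelVolume:
    """Integer grid over {0: background, 1: LA, 2: EAT}."""

    labels: np.ndarray
    spacing: tuple
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise InputError(f"labels outside {{0,1,2}}: {sorted(bad)}")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self):
        return self.labels.shape


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.25, 1.25, 2.5)
    la_radii: tuple = (16.0, 14.0, 20.0)   # mm semi-axes
    wall_thickness: float = 2.5            # mm
    eat_fraction_of_wall: float = 0.35     # fraction of wall surface carrying fat
    eat_thickness: float = 4.0             # mm
    distractor_count: int = 3
    distractor_radius: float = 5.0         # mm
    noise_sigma: float = 0.02              # additive Gaussian, fraction of signal
    seed: int = 0

    def validate(self):
        fov = np.asarray(self.shape) * np.asarray(self.spacing)
        margin = max(self.wall_thickness + self.eat_thickness, 1.0)
        if np.any(2 * (np.asarray(self.la_radii) + margin) >= fov):
            raise ConfigurationError(
                f"LA ellipsoid (radii {self.la_radii} mm + rind) does not fit the "
                f"field of view {tuple(fov)} mm")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")


@dataclass
class PhantomSample:
    volume: SegVolume
    labels: LabelVolume
    config: PhantomConfig


def _ellipsoid_level(coords_mm, center_mm, radii_mm):
    """Level function: < 1 inside the ellipsoid."""
    return sum(((c - mu) / r) ** 2
               for c, mu, r in zip(coords_mm, center_mm, radii_mm))


def _smooth_noise_field(rng, shape, sigma_vox=4.0):
    f = rng.normal(size=shape)
    f = ndimage.gaussian_filter(f, sigma=sigma_vox)
    return (f - f.mean()) / max(f.std(), 1e-9)


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Deterministic phantom with labels {0, 1 (LA incl. wall), 2 (EAT)}."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    spacing = tuple(cfg.spacing)
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    fov = [n * s for n, s in zip(shape, spacing)]
    center = [f / 2 + rng.uniform(-0.03, 0.03) * f for f in fov]

    lvl_blood = _ellipsoid_level(coords, center, cfg.la_radii)
    wall_radii = [r + cfg.wall_thickness for r in cfg.la_radii]
    lvl_wall = _ellipsoid_level(coords, center, wall_radii)
    rind_radii = [r + cfg.eat_thickness for r in wall_radii]
    lvl_rind = _ellipsoid_level(coords, center, rind_radii)

    blood = lvl_blood < 1.0
    wall = (lvl_wall < 1.0) & ~blood
    rind = (lvl_rind < 1.0) & (lvl_wall >= 1.0)

    # patchy EAT: keep the rind where a smooth random field exceeds the
    # quantile that leaves eat_fraction_of_wall of the rind covered
    eat = np.zeros(shape, dtype=bool)
    if cfg.eat_fraction_of_wall > 0 and rind.any():
        fieldv = _smooth_noise_field(rng, shape)
        thr = np.quantile(fieldv[rind], 1.0 - cfg.eat_fraction_of_wall)
        eat = rind & (fieldv >= thr)

    # distractor fat blobs >= 10 mm away from the outer LA surface
    la_region = lvl_wall < 1.0
    dist_mm = ndimage.distance_transform_edt(~la_region, sampling=spacing)
    distractor = np.zeros(shape, dtype=bool)
    candidates = np.argwhere(dist_mm >= 10.0 + cfg.distractor_radius)
    for _ in range(cfg.distractor_count):
        if len(candidates) == 0:
            break
        idx = candidates[rng.integers(len(candidates))]
        c_mm = [i * s for i, s in zip(idx, spacing)]
        blob = _ellipsoid_level(coords, c_mm, [cfg.distractor_radius] * 3) < 1.0
        distractor |= blob & (dist_mm >= 10.0)

    labels = np.zeros(shape, dtype=np.int16)
    labels[la_region] = 1
    labels[eat] = 2

    water = np.empty(shape)
    fat = np.empty(shape)
    bg_w, bg_f = TISSUE_SIGNALS["background"]
    tex = _smooth_noise_field(rng, shape, sigma_vox=6.0) * 0.05
    water[:], fat[:] = bg_w, bg_f
    water += tex
    fat -= tex
    for mask, tissue in ((blood, "blood"), (wall, "wall"),
                         (eat, "eat"), (distractor, "distractor")):
        w, f = TISSUE_SIGNALS[tissue]
        water[mask] = w
        fat[mask] = f

    if cfg.noise_sigma > 0:
        water = water + rng.normal(scale=cfg.noise_sigma, size=shape)
        fat = fat + rng.normal(scale=cfg.noise_sigma, size=shape)
    water = np.clip(water, 0.0, None)
    fat = np.clip(fat, 0.0, None)
    ff = np.clip(fat / (fat + water + 1e-8), 0.0, 1.0)

    volume = SegVolume({"water": water, "fat": fat, "fat_fraction": ff}, spacing)
    return PhantomSample(volume, LabelVolume(labels, spacing), cfg)


_JITTERED = ("la_radii", "wall_thickness", "eat_thickness", "eat_fraction_of_wall",
             "distractor_radius")


def generate_dataset(n: int, cfg: PhantomConfig | None = None,
                     seed: int = 0, jitter: float = 0.2) -> list:
    """``n`` phantoms with geometry jittered +/-``jitter`` around ``cfg``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    base = cfg or PhantomConfig()
    samples = []
    seeds = np.random.SeedSequence(seed).spawn(n)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        fields = dataclasses.asdict(base)
        for name in _JITTERED:
            val = fields[name]
            if isinstance(val, tuple):
                fields[name] = tuple(v * (1 + rng.uniform(-jitter, jitter))
                                     for v in val)
            else:
                fields[name] = val * (1 + rng.uniform(-jitter, jitter))
        fields["eat_fraction_of_wall"] = min(fields["eat_fraction_of_wall"], 1.0)
        fields["seed"] = int(rng.integers(2 ** 31))
        samples.append(generate_phantom(PhantomConfig(**fields)))
    return samples


# ---------------------------------------------------------------------------
# balanced patches & augmentation
# ---------------------------------------------------------------------------

def sample_balanced_patches(sample: PhantomSample, patch: int, n: int,
                            seed: int = 0) -> list:
    """``n`` (SegVolume, LabelVolume) cubes whose centers cycle through the
    classes EAT -> LA -> background, so minority classes appear in every
    mini-batch; patches are shifted to stay fully inside the grid."""
    shape = sample.labels.shape
    if any(patch > s for s in shape):
        raise ConfigurationError(f"patch {patch} exceeds grid {shape}")
    rng = np.random.default_rng(seed)
    labels = sample.labels.labels
    locs = {c: np.argwhere(labels == c) for c in (2, 1, 0)}
    stacked = sample.volume.stacked()

    def cut(center):
        starts = [int(np.clip(c - patch // 2, 0, s - patch))
                  for c, s in zip(center, shape)]
        return tuple(slice(st, st + patch) for st in starts)

    tally = {1: 0, 2: 0}
    out = []
    for i in range(n):
        # every third patch is background-centred; the rest go to whichever
        # foreground class is behind in cumulative voxel tally (EAT first),
        # which keeps LA and EAT voxel counts of a draw comparable
        if i % 3 == 2 and len(locs[0]):
            cls = 0
        elif len(locs[2]) and (not len(locs[1]) or tally[2] <= tally[1]):
            cls = 2
        elif len(locs[1]):
            cls = 1
        else:
            cls = next(c for c in (2, 0) if len(locs[c]))
        if cls == 2:
            # several candidate centres; keep the EAT-richest patch
            cands = [cut(locs[2][rng.integers(len(locs[2]))]) for _ in range(4)]
            sl = max(cands, key=lambda s: int((labels[s] == 2).sum()))
        else:
            sl = cut(locs[cls][rng.integers(len(locs[cls]))])
        lab = labels[sl].copy()
        for c in (1, 2):
            tally[c] += int((lab == c).sum())
        chans = {name: stacked[j][sl].copy() for j, name in enumerate(CHANNEL_ORDER)}
        out.append((SegVolume(chans, sample.volume.spacing),
                    LabelVolume(lab, sample.labels.spacing)))
    return out


def apply_augmentation(image: np.ndarray, labels: np.ndarray,
                       flips=(False, False, False), k_rot: int = 0,
                       scale: float = 1.0):
    """Deterministic transform: axis flips, in-plane 90-degree rotations and
    isotropic scaling (linear for channels, nearest for labels).

    ``image`` is channel-first ``(C, D, H, W)``; ``labels`` is ``(D, H, W)``.
    Identity parameters return the inputs unchanged.
    """
    img = np.asarray(image, dtype=float)
    lab = np.asarray(labels)
    for ax, flip in enumerate(flips):
        if flip:
            img = np.flip(img, axis=ax + 1)
            lab = np.flip(lab, axis=ax)
    if k_rot % 4:
        img = np.rot90(img, k=k_rot, axes=(1, 2))
        lab = np.rot90(lab, k=k_rot, axes=(0, 1))
    if scale != 1.0:
        shape = lab.shape
        zoomed = [ndimage.zoom(c, scale, order=1) for c in img]
        lab = ndimage.zoom(lab, scale, order=0)
        img = np.stack([_fit_to(c, shape) for c in zoomed])
        lab = _fit_to(lab, shape)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _fit_to(arr: np.ndarray, shape):
    """Center-crop / zero-pad ``arr`` to ``shape``."""
    out = np.zeros(shape, dtype=arr.dtype)
    src, dst = [], []
    for a, s in zip(arr.shape, shape):
        if a >= s:
            start = (a - s) // 2
            src.append(slice(start, start + s))
            dst.append(slice(0, s))
        else:
            start = (s - a) // 2
            src.append(slice(0, a))
            dst.append(slice(start, start + a))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def augment(image: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Random flip / 90-degree in-plane rotation / scaling in [0.9, 1.1]."""
    rng = np.random.default_rng(seed)
    flips = tuple(bool(rng.integers(2)) for _ in range(3))
    k_rot = int(rng.integers(4))
    scale = float(rng.uniform(0.9, 1.1))
    return apply_augmentation(image, labels, flips, k_rot, scale)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _spacing_from(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(paths) -> SegVolume:
    """Read a SegVolume from three per-channel NIfTI files (dict or sequence
    in the order water, fat, fat_fraction) or one 4-D channel-last file."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        img = nib.load(str(paths))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 4 or arr.shape[-1] != len(CHANNEL_ORDER):
            raise InputError(
                f"expected a 4-D volume with {len(CHANNEL_ORDER)} channels, got {arr.shape}")
        channels = {name: np.ascontiguousarray(arr[..., i], dtype=float)
                    for i, name in enumerate(CHANNEL_ORDER)}
        return SegVolume(channels, _spacing_from(img), affine=img.affine)
    if isinstance(paths, dict):
        items = [(name, paths[name]) for name in CHANNEL_ORDER]
    else:
        items = list(zip(CHANNEL_ORDER, paths))
    channels, spacings, affine = {}, [], None
    for name, path in items:
        try:
            img = nib.load(str(path))
        except FileNotFoundError as e:
            raise InputError(f"missing channel file for {name!r}: {path}") from e
        channels[name] = np.asanyarray(img.dataobj).astype(float)
        spacings.append(_spacing_from(img))
        affine = img.affine if affine is None else affine
    if len({channels[n].shape for n in channels}) > 1:
        raise InputError("channel files have inconsistent shapes: "
                         + str({n: channels[n].shape for n in channels}))
    if len(set(spacings)) > 1:
        raise InputError(f"channel files have inconsistent spacings: {spacings}")
    return SegVolume(channels, spacings[0], affine=affine)


def write_volume(vol: SegVolume, path) -> None:
    """Write a SegVolume as one 4-D channel-last NIfTI file."""
    arr = np.stack([vol.channels[name] for name in CHANNEL_ORDER], axis=-1)
    nib.save(nib.Nifti1Image(arr.astype(np.float32), vol.affine), str(path))


def read_labels(path) -> LabelVolume:
    try:
        img = nib.load(str(path))
    except FileNotFoundError as e:
        raise InputError(f"missing label file: {path}") from e
    arr = np.asanyarray(img.dataobj).astype(np.int16)
    return LabelVolume(arr, _spacing_from(img), affine=img.affine)


def write_labels(lab: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(lab.labels.astype(np.int16), lab.affine), str(path))
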