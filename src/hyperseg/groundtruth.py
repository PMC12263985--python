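"""Semi-automatic EAT reference labels: fat-fraction normalization,
thresholding at 0.4 and intersection with a supplied fat ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

DEFAULT_THRESHOLD = 0.4

__all__ = ["FatFractionMap", "normalize_fat_fraction", "threshold_eat",
           "combine_with_roi", "eat_reference_mask", "DEFAULT_THRESHOLD"]


@dataclass
class FatFractionMap:
    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise InputError("fat fraction values must lie in [0, 1]")


def normalize_fat_fraction(raw: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> FatFractionMap:
    """Divide by the per-volume maximum; an all-zero grid stays all-zero."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise InputError("fat fraction input must be finite")
    if raw.size and raw.min() < 0:
        raise InputError("fat fraction input must be non-negative")
    m = raw.max() if raw.size else 0.0
    values = raw / m if m > 0 else np.zeros_like(raw)
    return FatFractionMap(values, tuple(spacing))


def threshold_eat(ff: FatFractionMap, thr: float = DEFAULT_THRESHOLD,
                  strict: bool = True) -> np.ndarray:
    """Binary mask of voxels whose fat fraction *exceeds* ``thr`` (strict >)."""
    if not (0.0 <= thr <= 1.0):
        raise ConfigurationError(f"threshold must lie in [0, 1], got {thr}")
    v = ff.values if isinstance(ff, FatFractionMap) else np.asarray(ff, dtype=float)
    return (v > thr) if strict else (v >= thr)


def combine_with_roi(eat_mask: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Voxel-wise AND of the threshold mask with the (manual) fat ROI."""
    eat_mask = np.asarray(eat_mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if eat_mask.shape != roi.shape:
        raise InputError(f"shape mismatch: mask {eat_mask.shape} vs ROI {roi.shape}")
    return eat_mask & roi


def eat_reference_mask(raw_fat_fraction: np.ndarray, roi: np.ndarray,
                       thr: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Full pipeline: normalize -> threshold -> intersect with ROI."""
    ff = normalize_fat_fraction(raw_fat_fraction)
    return combine_with_roi(threshold_eat(ff, thr), roi)
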