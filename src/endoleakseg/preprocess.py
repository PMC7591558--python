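"""Deterministic image normalisation applied before training and inference.

Three steps, in order: clamp raw HU values to a display-like window, resize to
the model's input resolution, and mean-center.  Mean-centering defaults to a
single dataset mean estimated on training slices only (no test-set leakage);
per-slice centering is available as an option.  Masks are resized with
nearest-neighbour interpolation so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from skimage.transform import resize as _sk_resize

PER_SLICE = "per_slice"
DATASET = "dataset"


@dataclass
class PreprocessSpec:
    """Normalisation settings persisted with a trained model.

    clamp_lo/clamp_hi — HU window bounds (default [-1024, 1024], a typical
    CTA display range); target_size — square model input resolution;
    center_mode — 'dataset' (subtract a training-set mean) or 'per_slice';
    dataset_mean/dataset_std — required iff center_mode='dataset', fitted via
    :func:`fit_dataset_stats` on training slices only.  After centering,
    pixels are divided by the SD so the network sees unit-scale inputs
    (set normalize=False for raw HU offsets).
    """

    clamp_lo: float = -1024.0
    clamp_hi: float = 1024.0
    target_size: int = 64
    center_mode: str = DATASET
    dataset_mean: Optional[float] = None
    dataset_std: Optional[float] = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.clamp_lo >= self.clamp_hi:
            raise ValueError("clamp_lo must be < clamp_hi")
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.center_mode not in (PER_SLICE, DATASET):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")


def clamp_pixels(pixels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Elementwise clamp to [lo, hi]; idempotent; shape unchanged."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    return np.clip(pixels, lo, hi)


def resize(grid: np.ndarray, target_size: int, kind: str = "image") -> np.ndarray:
    """Resize a square-or-not grid to target_size×target_size.

    Images use smooth (bilinear, anti-aliased) interpolation; masks use
    nearest-neighbour and remain strictly binary.  Resizing to the grid's own
    size is the exact identity for masks.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if grid.shape == (target_size, target_size):
        return grid.copy()
    if kind == "mask":
        out = _sk_resize(grid.astype(np.uint8), (target_size, target_size),
                         order=0, preserve_range=True, anti_aliasing=False)
        return (out > 0.5).astype(np.uint8)
    if kind != "image":
        raise ValueError("kind must be 'image' or 'mask'")
    return _sk_resize(grid.astype(np.float64), (target_size, target_size),
                      order=1, preserve_range=True, anti_aliasing=True)


def fit_dataset_stats(slices: Iterable[np.ndarray], lo: float,
                      hi: float) -> tuple[float, float]:
    """Mean and SD of clamped training-slice pixels (training data only)."""
    total, total2, count = 0.0, 0.0, 0
    for px in slices:
        c = clamp_pixels(np.asarray(px, dtype=np.float64), lo, hi)
        total += c.sum()
        total2 += (c * c).sum()
        count += c.size
    if count == 0:
        raise ValueError("cannot fit dataset statistics on an empty input")
    mean = total / count
    var = max(total2 / count - mean * mean, 0.0)
    return mean, float(np.sqrt(var))


def fit_dataset_mean(slices: Iterable[np.ndarray], lo: float, hi: float) -> float:
    """Mean pixel value over clamped training slices (fit on training data only)."""
    return fit_dataset_stats(slices, lo, hi)[0]


def mean_center(pixels: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Subtract the per-slice mean or the fitted dataset mean."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty input")
    if spec.center_mode == PER_SLICE:
        return pixels - pixels.mean()
    if spec.dataset_mean is None:
        raise ValueError("center_mode='dataset' requires a fitted dataset_mean")
    return pixels - spec.dataset_mean


def preprocess_slice(pixels: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """clamp → resize → mean-center (→ unit-scale); float64 at spec.target_size."""
    out = clamp_pixels(np.asarray(pixels, dtype=np.float64),
                       spec.clamp_lo, spec.clamp_hi)
    out = resize(out, spec.target_size, kind="image")
    if not spec.normalize:
        return mean_center(out, spec)
    if spec.center_mode == PER_SLICE:
        sd = out.std()
        return (out - out.mean()) / (sd if sd > 0 else 1.0)
    if spec.dataset_mean is None or spec.dataset_std is None:
        raise ValueError("center_mode='dataset' requires fitted dataset_mean/std")
    return (out - spec.dataset_mean) / (spec.dataset_std if spec.dataset_std > 0
                                        else 1.0)


def preprocess_mask(mask: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    return resize(mask, spec.target_size, kind="mask")
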