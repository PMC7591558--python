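"""Lesion-aware training augmentation: mask-bounded endoleak insertion/removal.

The augmentor turns one labeled slice into paired training examples.  To make
a positive from a control-like slice, a random-shaped blob bounded by the
aneurysm-sac mask is filled with draws from the Gaussian fitted to labeled
endoleak pixels (mean ``u_e``, SD ``sigma_e``).  To make a negative from a
positive, the pixels under the endoleak mask are replaced with draws from the
Gaussian fitted to sac-thrombus pixels (``u_a``, ``sigma_a``).  Either way the
rest of the slice is untouched, so the pair is anatomically identical except
for the lesion — the model is forced to learn the lesion, not the anatomy.

A batch dispatcher applies add / remove / pass-through per slice according to
an augment ID, with per-element seeds derived from one master seed.  Standard
rotation + pixel-noise augmentation is also provided.  All intensity sampling
happens in native HU, before any clamping or centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .shapes import random_blob
from .types import CaseRecord, CTSlice, MaskSet

ADD = "ADD"
REMOVE = "REMOVE"
NONE = "NONE"


class IntensityDataError(ValueError):
    """Not enough labeled pixels to fit an intensity model."""


@dataclass
class IntensityStats:
    """Gaussian pixel models for endoleak and aneurysm-sac thrombus (HU).

    u_e/sigma_e — mean and SD over all labeled endoleak pixels; u_a/sigma_a —
    over sac pixels excluding the stent lumen and any labeled endoleak;
    n_e/n_a — pixel counts the estimates pooled over.
    """

    u_e: float
    sigma_e: float
    u_a: float
    sigma_a: float
    n_e: int
    n_a: int

    def __post_init__(self) -> None:
        if self.sigma_e < 0 or self.sigma_a < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_e <= 0 or self.n_a <= 0:
            raise ValueError("pixel counts must be positive")

    def to_dict(self) -> dict:
        return {"u_e": self.u_e, "sigma_e": self.sigma_e, "u_a": self.u_a,
                "sigma_a": self.sigma_a, "n_e": self.n_e, "n_a": self.n_a}

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityStats":
        return cls(**d)


@dataclass
class ShapeSpec:
    """Parameters of the random inserted-lesion shape.

    area_range — (min, max) lesion area in pixels; None defers to a fraction
    of the allowed region's area (area_fraction_range) at call time, so one
    spec works across image resolutions.  exclude_lumen — inserted lesions
    avoid the stent lumen (an endoleak is outside the graft by definition).
    """

    area_range: Optional[tuple[int, int]] = None
    area_fraction_range: tuple[float, float] = (0.05, 0.25)
    n_ellipses_range: tuple[int, int] = (2, 5)
    closing_radius: int = 1
    exclude_lumen: bool = True
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.area_range is not None:
            lo, hi = self.area_range
            if not (0 < lo < hi):
                raise ValueError("area_range must satisfy 0 < min < max")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    def resolve_area_range(self, allowed_area: int) -> tuple[int, int]:
        if self.area_range is not None:
            return self.area_range
        lo = max(4, int(round(self.area_fraction_range[0] * allowed_area)))
        hi = max(lo + 1, int(round(self.area_fraction_range[1] * allowed_area)))
        return lo, hi


@dataclass
class AugmentBatch:
    """A batch of slices+masks with one augment ID (ADD/REMOVE/NONE) each."""

    slices: list[CTSlice]
    masks: list[MaskSet]
    augment_ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.slices) == len(self.masks) == len(self.augment_ids)):
            raise ValueError("slices, masks and augment_ids must have equal length")
        bad = set(self.augment_ids) - {ADD, REMOVE, NONE}
        if bad:
            raise ValueError(f"unknown augment IDs {sorted(bad)}")


@dataclass
class AugmentResult:
    """Transformed slices and their binary endoleak target maps."""

    out_slices: list[np.ndarray]
    out_labels: list[np.ndarray]


def estimate_intensity_stats(cases: Sequence[CaseRecord]) -> IntensityStats:
    """Pool endoleak and sac pixels over training cases and fit the Gaussians.

    Sac pixels exclude the stent lumen and labeled endoleak regions.  Raises
    :class:`IntensityDataError` naming the missing class if either pool is
    empty.
    """
    leak_px, sac_px = [], []
    for case in cases:
        for sl, ms in zip(case.slices, case.masks):
            px = np.asarray(sl.pixels, dtype=np.float64)
            if ms.endoleak is not None and ms.endoleak.any():
                leak_px.append(px[ms.endoleak == 1])
            if ms.aneurysm_sac is not None:
                sac = ms.aneurysm_sac.astype(bool)
                if ms.stent_lumen is not None:
                    sac &= ~ms.stent_lumen.astype(bool)
                if ms.endoleak is not None:
                    sac &= ~ms.endoleak.astype(bool)
                if sac.any():
                    sac_px.append(px[sac])
    if not leak_px:
        raise IntensityDataError("no labeled endoleak pixels in training cases")
    if not sac_px:
        raise IntensityDataError("no qualifying aneurysm-sac pixels in training cases")
    leak = np.concatenate(leak_px)
    sac = np.concatenate(sac_px)
    return IntensityStats(u_e=float(leak.mean()), sigma_e=float(leak.std()),
                          u_a=float(sac.mean()), sigma_a=float(sac.std()),
                          n_e=int(leak.size), n_a=int(sac.size))


def generate_random_endoleak_shape(sac_mask: np.ndarray,
                                   lumen_mask: Optional[np.ndarray],
                                   shape_spec: ShapeSpec,
                                   seed: int) -> np.ndarray:
    """Random single-component lesion mask inside the sac (minus lumen)."""
    allowed = np.asarray(sac_mask).astype(bool)
    if shape_spec.exclude_lumen and lumen_mask is not None:
        allowed &= ~np.asarray(lumen_mask).astype(bool)
    area_range = shape_spec.resolve_area_range(int(allowed.sum()))
    rng = np.random.default_rng(seed)
    return random_blob(allowed, area_range, rng,
                       n_ellipses_range=shape_spec.n_ellipses_range,
                       closing_radius=shape_spec.closing_radius,
                       max_attempts=shape_spec.max_attempts)


def insert_endoleak(pixels: np.ndarray, shape: np.ndarray,
                    u_e: float, sigma_e: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Fill ``shape`` with independent N(u_e, sigma_e²) draws; rest untouched."""
    out = np.asarray(pixels, dtype=np.float64).copy()
    m = np.asarray(shape).astype(bool)
    out[m] = rng.normal(u_e, sigma_e, int(m.sum()))
    return out


def augment_adder(pixels: np.ndarray, sac_mask: np.ndarray,
                  u_e: float, sigma_e: float,
                  shape_spec: ShapeSpec | None = None,
                  seed: int = 0,
                  lumen_mask: Optional[np.ndarray] = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Insert a random endoleak bounded by the sac mask.

    Returns the augmented slice and its new target map (the inserted shape).
    Pixels outside the shape are numerically identical to the input.
    """
    spec = shape_spec if shape_spec is not None else ShapeSpec()
    shape = generate_random_endoleak_shape(sac_mask, lumen_mask, spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1))
    return insert_endoleak(pixels, shape, u_e, sigma_e, rng), shape


def augment_remover(pixels: np.ndarray, endoleak_mask: Optional[np.ndarray],
                    u_a: float, sigma_a: float,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Replace endoleak pixels with sac-Gaussian draws; target map all-zero."""
    px = np.asarray(pixels, dtype=np.float64)
    if endoleak_mask is None or not np.asarray(endoleak_mask).any():
        warnings.warn("augment_remover called with an empty endoleak mask; no-op")
        return px.copy(), np.zeros(px.shape, dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1))
    out = insert_endoleak(px, endoleak_mask, u_a, sigma_a, rng)
    return out, np.zeros(px.shape, dtype=np.uint8)


def augment_batch(batch: AugmentBatch, stats: IntensityStats,
                  shape_spec: ShapeSpec | None = None,
                  seed: int = 0) -> AugmentResult:
    """Dispatch each batch element by its augment ID; order preserved.

    Per-element seeds derive from (seed, element index), so the whole result
    is reproducible from one master seed.  A precondition violation (ADD with
    no sac mask, REMOVE with no endoleak mask) rejects the batch, naming the
    offending index.
    """
    spec = shape_spec if shape_spec is not None else ShapeSpec()
    for b, (ms, lid) in enumerate(zip(batch.masks, batch.augment_ids)):
        if lid == ADD and (ms.aneurysm_sac is None or not ms.aneurysm_sac.any()):
            raise ValueError(f"batch element {b}: ADD requires a non-empty sac mask")
        if lid == REMOVE and (ms.endoleak is None or not ms.endoleak.any()):
            raise ValueError(f"batch element {b}: REMOVE requires a non-empty endoleak mask")

    out_slices, out_labels = [], []
    for b, (sl, ms, lid) in enumerate(zip(batch.slices, batch.masks, batch.augment_ids)):
        sub = int(np.random.SeedSequence([seed, b]).generate_state(1)[0] & 0x7FFFFFFF)
        px = np.asarray(sl.pixels, dtype=np.float64)
        if lid == ADD:
            x, y = augment_adder(px, ms.aneurysm_sac, stats.u_e, stats.sigma_e,
                                 spec, sub, lumen_mask=ms.stent_lumen)
        elif lid == REMOVE:
            x, y = augment_remover(px, ms.endoleak, stats.u_a, stats.sigma_a, sub)
        else:
            x = px.copy()
            y = (ms.endoleak.copy() if ms.endoleak is not None
                 else np.zeros(px.shape, dtype=np.uint8))
        out_slices.append(x)
        out_labels.append(y.astype(np.uint8))
    return AugmentResult(out_slices=out_slices, out_labels=out_labels)


def standard_augment(pixels: np.ndarray, label_map: np.ndarray,
                     rotation_range_deg: float, noise_sigma: float,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random rotation (shared by image and label) plus image-only pixel noise.

    The image is rotated with bilinear interpolation, the label map with
    nearest-neighbour so it stays binary.  rotation_range_deg=0 and
    noise_sigma=0 is the exact identity.
    """
    if rotation_range_deg < 0 or noise_sigma < 0:
        raise ValueError("rotation range and noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.asarray(pixels, dtype=np.float64)
    lab = np.asarray(label_map)
    angle = rng.uniform(-rotation_range_deg, rotation_range_deg)
    if angle != 0.0:
        img = _sk_rotate(img, angle, order=1, preserve_range=True,
                         mode="constant", cval=float(np.median(img)))
        lab = (_sk_rotate(lab.astype(float), angle, order=0, preserve_range=True,
                          mode="constant", cval=0.0) > 0.5)
    else:
        img = img.copy()
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return img, lab.astype(np.uint8)
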