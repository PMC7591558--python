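"""Domain containers for post-EVAR CTA slices, masks, cases and cohort splits.

Pixel grids are HU-like signed attenuation values.  Masks are binary uint8
arrays co-registered with their slice.  A case is one patient's slice stack
with per-slice masks and a case-level endoleak label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

POSITIVE = "positive"
CONTROL = "control"


class MaskAlignmentError(ValueError):
    """A mask disagrees with its slice geometry or containment rules."""


@dataclass
class CTSlice:
    """One 2-D grid of attenuation values with its provenance.

    Parameters
    ----------
    pixels : 2-D float array (HU-like, signed)
    case_id : opaque case identifier
    slice_index : integer position within the case, >= 0
    pixel_spacing : (row, col) millimetres per pixel
    """

    pixels: np.ndarray
    case_id: str
    slice_index: int
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing entries must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_binary(mask: Optional[np.ndarray], name: str) -> Optional[np.ndarray]:
    if mask is None:
        return None
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} mask must contain only 0/1, got values {vals}")
    return mask.astype(np.uint8)


@dataclass
class MaskSet:
    """Co-registered binary masks for one slice: aneurysm sac, stent lumen, endoleak.

    Any mask may be absent (None).  When both are present the stent lumen must
    lie inside the aneurysm sac.
    """

    aneurysm_sac: Optional[np.ndarray] = None
    stent_lumen: Optional[np.ndarray] = None
    endoleak: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.aneurysm_sac = _as_binary(self.aneurysm_sac, "aneurysm_sac")
        self.stent_lumen = _as_binary(self.stent_lumen, "stent_lumen")
        self.endoleak = _as_binary(self.endoleak, "endoleak")
        shapes = {m.shape for m in (self.aneurysm_sac, self.stent_lumen, self.endoleak)
                  if m is not None}
        if len(shapes) > 1:
            raise MaskAlignmentError(f"masks have inconsistent shapes: {shapes}")
        if self.aneurysm_sac is not None and self.stent_lumen is not None:
            if np.any(self.stent_lumen & ~self.aneurysm_sac):
                raise MaskAlignmentError("stent lumen extends outside the aneurysm sac")

    def validate_against(self, sl: CTSlice) -> None:
        for name in ("aneurysm_sac", "stent_lumen", "endoleak"):
            m = getattr(self, name)
            if m is not None and m.shape != sl.shape:
                raise MaskAlignmentError(
                    f"{name} mask shape {m.shape} != slice shape {sl.shape}")

    @property
    def has_endoleak(self) -> bool:
        return self.endoleak is not None and bool(self.endoleak.any())


@dataclass
class CaseRecord:
    """One patient's CTA: ordered slices, per-slice masks, case-level label."""

    case_id: str
    slices: list[CTSlice]
    masks: list[MaskSet]
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, CONTROL):
            raise ValueError(f"label must be '{POSITIVE}' or '{CONTROL}'")
        if len(self.slices) != len(self.masks):
            raise ValueError("one MaskSet required per slice")
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice_index must be strictly increasing")
        for sl, ms in zip(self.slices, self.masks):
            ms.validate_against(sl)
        any_leak = any(ms.has_endoleak for ms in self.masks)
        if (self.label == POSITIVE) != any_leak:
            raise ValueError(
                "label 'positive' iff at least one slice has a non-empty endoleak mask")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test case-id lists plus the seed that made them."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        all_ids = self.train + self.validation + self.test
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("split lists must be disjoint with no repeats")


def split_cohort(cases: Sequence[CaseRecord],
                 n_train_pos: int, n_train_neg: int,
                 n_val_pos: int, n_val_neg: int,
                 n_test_pos: int, n_test_neg: int,
                 seed: int = 0) -> DatasetSplit:
    """Class-stratified random partition of a cohort into train/val/test.

    Requested per-class counts must sum exactly to the available counts.
    Deterministic under ``seed``.
    """
    pos = sorted(c.case_id for c in cases if c.label == POSITIVE)
    neg = sorted(c.case_id for c in cases if c.label == CONTROL)
    if n_train_pos + n_val_pos + n_test_pos != len(pos):
        raise ValueError(
            f"positive counts {(n_train_pos, n_val_pos, n_test_pos)} do not sum to "
            f"{len(pos)} available")
    if n_train_neg + n_val_neg + n_test_neg != len(neg):
        raise ValueError(
            f"control counts {(n_train_neg, n_val_neg, n_test_neg)} do not sum to "
            f"{len(neg)} available")
    rng = np.random.default_rng(seed)
    pos = list(rng.permutation(pos))
    neg = list(rng.permutation(neg))
    train = pos[:n_train_pos] + neg[:n_train_neg]
    val = pos[n_train_pos:n_train_pos + n_val_pos] + neg[n_train_neg:n_train_neg + n_val_neg]
    test = pos[n_train_pos + n_val_pos:] + neg[n_train_neg + n_val_neg:]
    return DatasetSplit(train=train, validation=val, test=test, seed=seed)


def select_cases(cases: Sequence[CaseRecord], ids: Sequence[str]) -> list[CaseRecord]:
    by_id = {c.case_id: c for c in cases}
    return [by_id[i] for i in ids]
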