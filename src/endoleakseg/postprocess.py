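"""From probability maps to slice calls and a per-case endoleak decision.

Three stages: (1) pick the probability threshold on the validation set by
maximising slice-level F1; (2) binarise each map and drop connected components
that are implausibly small or large; (3) aggregate surviving slice calls into
one case decision, either by total count or by the longest consecutive-slice
run of positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label

from .segmentation import SliceProbMap

RULE_COUNT = "count"
RULE_RUN = "run"


@dataclass
class PostprocessSpec:
    """Decision-stage settings persisted with a trained model.

    min_area_px/max_area_px — inclusive component-area bounds for a plausible
    endoleak (defaults: 10 px minimum, 20% of a 64² image maximum);
    case_rule — 'run' requires case_k consecutive positive slices (an endoleak
    persists across adjacent slices), 'count' requires case_k positives
    anywhere.  case_k defaults to 2: sensitive to a minimal two-slice lesion
    while still suppressing isolated single-slice noise.
    """

    prob_threshold: float = 0.5
    min_area_px: int = 10
    max_area_px: int = 819
    case_rule: str = RULE_RUN
    case_k: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("need 0 < min_area_px < max_area_px")
        if self.case_rule not in (RULE_COUNT, RULE_RUN):
            raise ValueError(f"unknown case_rule {self.case_rule!r}")
        if self.case_k < 1:
            raise ValueError("case_k must be >= 1")


@dataclass
class SliceCall:
    case_id: str
    slice_index: int
    positive: bool
    surviving_area_px: int

    def __post_init__(self) -> None:
        if self.positive != (self.surviving_area_px > 0):
            raise ValueError("positive iff surviving area > 0")


@dataclass
class CaseDecision:
    case_id: str
    positive: bool
    n_positive_slices: int
    longest_run: int


def select_threshold(prob_maps: Sequence[SliceProbMap],
                     truth_masks: Sequence[np.ndarray],
                     grid: Sequence[float]) -> tuple[float, dict]:
    """Grid value maximising slice-level F1 on the validation set.

    A slice counts as predicted-positive at threshold t iff any pixel
    probability reaches t; truly positive iff its endoleak mask is non-empty.
    Ties in F1 break toward the higher threshold.  Returns the threshold and
    the precision/recall/F1 achieved at it.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("threshold grid is empty")
    if len(prob_maps) != len(truth_masks):
        raise ValueError("one truth mask required per probability map")
    truth = np.array([bool(np.asarray(m).any()) for m in truth_masks])
    if not truth.any():
        raise ValueError("no positive slices in the validation set")
    peak = np.array([float(np.max(pm.probs)) for pm in prob_maps])

    best = None
    for t in grid:
        pred = peak >= t
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        f1 = 0.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
        if best is None or f1 >= best[0]:  # >= ties toward higher threshold
            prec = float("nan") if tp + fp == 0 else tp / (tp + fp)
            rec = tp / (tp + fn)
            best = (f1, t, {"f1": f1, "precision": prec, "recall": rec})
    return best[1], best[2]


def size_filter(binary_map: np.ndarray, min_area_px: int,
                max_area_px: int) -> np.ndarray:
    """Remove 4-connected components with area outside [min, max] (inclusive)."""
    m = np.asarray(binary_map).astype(bool)
    lbl = cc_label(m, connectivity=1)
    if lbl.max() == 0:
        return np.zeros_like(m, dtype=np.uint8)
    areas = np.bincount(lbl.ravel())
    keep = (areas >= min_area_px) & (areas <= max_area_px)
    keep[0] = False
    return keep[lbl].astype(np.uint8)


def call_slices(prob_maps: Sequence[SliceProbMap],
                spec: PostprocessSpec) -> list[SliceCall]:
    """Binarise at the threshold, size-filter, call positive iff pixels survive."""
    calls = []
    for pm in prob_maps:
        surviving = size_filter(pm.probs >= spec.prob_threshold,
                                spec.min_area_px, spec.max_area_px)
        area = int(surviving.sum())
        calls.append(SliceCall(case_id=pm.case_id, slice_index=pm.slice_index,
                               positive=area > 0, surviving_area_px=area))
    return calls


def slice_score(pm: SliceProbMap, spec: PostprocessSpec) -> float:
    """Continuous slice score for ROC: max probability inside surviving
    components of the thresholded map, 0 if nothing survives."""
    surviving = size_filter(pm.probs >= spec.prob_threshold,
                            spec.min_area_px, spec.max_area_px)
    return float(pm.probs[surviving.astype(bool)].max()) if surviving.any() else 0.0


def decide_case(calls: Sequence[SliceCall], spec: PostprocessSpec) -> CaseDecision:
    """Aggregate one case's slice calls into a case-level endoleak decision."""
    if not calls:
        raise ValueError("need at least one slice call")
    ids = {c.case_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"mixed case_ids in one decision: {sorted(ids)}")
    ordered = sorted(calls, key=lambda c: c.slice_index)
    n_pos = sum(c.positive for c in ordered)
    longest = run = 0
    prev_idx = None
    for c in ordered:
        if c.positive:
            # a run requires contiguous slice indices, not just list adjacency
            run = run + 1 if prev_idx is not None and c.slice_index == prev_idx + 1 else 1
            prev_idx = c.slice_index
        else:
            run, prev_idx = 0, None
        longest = max(longest, run)
    if spec.case_rule == RULE_COUNT:
        positive = n_pos >= spec.case_k
    else:
        positive = longest >= spec.case_k
    return CaseDecision(case_id=ordered[0].case_id, positive=positive,
                        n_positive_slices=n_pos, longest_run=longest)
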