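"""Random irregular lesion shapes bounded by an allowed region.

A blob is the union of a few random ellipses anchored inside the allowed
region, intersected with it, smoothed by morphological closing, and reduced to
a single 4-connected component whose area lies in a requested range.
Rejection-sample until the constraints hold.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing, disk


class ShapeGenerationError(RuntimeError):
    """No valid lesion shape could be generated within the attempt budget."""


def ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                 theta: float = 0.0) -> np.ndarray:
    """Filled rotated ellipse on a size×size grid (uint8)."""
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * y + s * x) / ry
    v = (-s * y + c * x) / rx
    return (u * u + v * v <= 1.0).astype(np.uint8)


def random_blob(allowed: np.ndarray, area_range: tuple[int, int],
                rng: np.random.Generator,
                n_ellipses_range: tuple[int, int] = (2, 5),
                closing_radius: int = 1,
                max_attempts: int = 200) -> np.ndarray:
    """Draw one random blob inside ``allowed`` with area in ``area_range``.

    Returns a uint8 mask that is a subset of ``allowed`` and a single
    4-connected component.  Raises :class:`ShapeGenerationError` if the
    allowed region is too small or no attempt satisfies the constraints.
    """
    allowed = np.asarray(allowed).astype(bool)
    lo, hi = int(area_range[0]), int(area_range[1])
    if not (0 < lo < hi):
        raise ValueError("area_range must satisfy 0 < min < max")
    coords = np.argwhere(allowed)
    if coords.shape[0] < lo:
        raise ShapeGenerationError(
            f"allowed region ({coords.shape[0]} px) smaller than minimum area {lo}")
    size = allowed.shape[0]
    if allowed.shape[0] != allowed.shape[1]:
        # pad to square for the ellipse rasteriser, crop back afterwards
        size = max(allowed.shape)

    selem = disk(closing_radius) if closing_radius > 0 else None
    for _ in range(max_attempts):
        target = rng.uniform(lo, hi)
        n_ell = int(rng.integers(n_ellipses_range[0], n_ellipses_range[1] + 1))
        ay, ax = coords[rng.integers(coords.shape[0])]
        base_r = max(1.0, np.sqrt(target / (np.pi * n_ell)) * rng.uniform(0.9, 1.5))
        canvas = np.zeros((size, size), dtype=bool)
        for _ in range(n_ell):
            cy = ay + rng.normal(0, 0.8 * base_r)
            cx = ax + rng.normal(0, 0.8 * base_r)
            ry = base_r * rng.uniform(0.6, 1.6)
            rx = base_r * rng.uniform(0.6, 1.6)
            canvas |= ellipse_mask(size, cy, cx, ry, rx,
                                   rng.uniform(0, np.pi)).astype(bool)
        canvas = canvas[:allowed.shape[0], :allowed.shape[1]] & allowed
        if selem is not None:
            canvas = _closing(canvas, selem) & allowed
        lbl = cc_label(canvas, connectivity=1)
        if lbl.max() == 0:
            continue
        if lbl[ay, ax] > 0:
            comp = lbl == lbl[ay, ax]
        else:
            sizes = np.bincount(lbl.ravel())
            sizes[0] = 0
            comp = lbl == sizes.argmax()
        area = int(comp.sum())
        if lo <= area <= hi:
            return comp.astype(np.uint8)
    raise ShapeGenerationError(
        f"no valid shape with area in [{lo}, {hi}] after {max_attempts} attempts")
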