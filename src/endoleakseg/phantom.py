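"""Synthetic post-EVAR CTA phantom cohorts with exact ground-truth masks.

Each case is a short stack of 2-D slices containing an elliptical aneurysm sac
of mid-intensity thrombus, a bright circular stent lumen inside it, and — for
positive cases — a bright irregular endoleak blob painted into the sac (outside
the lumen) on a contiguous run of slices.  Region pixels are Gaussian draws;
zero-mean Gaussian noise is added everywhere; pixels are rounded to integer HU
(int16), matching how CT attenuation is stored.

Because noise is additive, the observed SD of a region is
``hypot(region_sigma, noise_sigma)`` — use :meth:`PhantomConfig.effective_sigma`
when checking parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CONTROL, POSITIVE, CaseRecord, CTSlice, MaskSet
from .shapes import ellipse_mask, random_blob


@dataclass
class PhantomConfig:
    """Generator settings; intensity units are HU.

    The default palette (background 0±15, sac 40±12, lumen 250±25,
    leak 180±25, noise 10) gives CTA-like contrast: contrast-enhanced
    regions (lumen, leak) are much brighter than thrombosed sac.
    """

    image_size: int = 64
    n_slices_per_case: int = 6
    background_mu: float = 0.0
    background_sigma: float = 15.0
    sac_mu: float = 40.0
    sac_sigma: float = 12.0
    lumen_mu: float = 250.0
    lumen_sigma: float = 25.0
    leak_mu: float = 180.0
    leak_sigma: float = 25.0
    leak_area_range: tuple[float, float] = (0.02, 0.15)  # fraction of sac area
    leak_slice_run: tuple[int, int] = (2, 5)  # consecutive slices carrying the leak
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lumen_mu > self.sac_mu and self.leak_mu > self.sac_mu):
            raise ValueError("lumen_mu and leak_mu must exceed sac_mu "
                             "(contrast-enhanced regions are brighter than sac)")
        lo, hi = self.leak_area_range
        if not (0 < lo < hi < 1):
            raise ValueError("leak_area_range must satisfy 0 < min < max < 1")
        if self.image_size < 16:
            raise ValueError("image_size too small for sac/lumen geometry")

    def effective_sigma(self, region: str) -> float:
        """Observed pixel SD of a region once additive noise is included."""
        base = getattr(self, f"{region}_sigma")
        return float(np.hypot(base, self.noise_sigma))


def _case_geometry(config: PhantomConfig, rng: np.random.Generator):
    """Sac ellipse and lumen circle for one case (shared across its slices)."""
    n = config.image_size
    cy = n / 2 + rng.uniform(-0.04, 0.04) * n
    cx = n / 2 + rng.uniform(-0.04, 0.04) * n
    ry = rng.uniform(0.24, 0.32) * n
    rx = rng.uniform(0.24, 0.32) * n
    theta = rng.uniform(0, np.pi)
    sac = ellipse_mask(n, cy, cx, ry, rx, theta)
    r_lum = rng.uniform(0.28, 0.38) * min(ry, rx)
    if r_lum >= min(ry, rx):
        raise ValueError("stent lumen does not fit inside the aneurysm sac")
    off = 0.25 * min(ry, rx)
    lum = ellipse_mask(n, cy + rng.uniform(-off, off), cx + rng.uniform(-off, off),
                        r_lum, r_lum)
    lum &= sac  # lumen strictly inside the sac
    return sac, lum


def generate_case(config: PhantomConfig, label: str, case_seed: int) -> CaseRecord:
    """Generate one phantom case; deterministic under ``case_seed``."""
    rng = np.random.default_rng(case_seed)
    n = config.image_size
    sac, lum = _case_geometry(config, rng)

    leak_mask = None
    leak_slices: set[int] = set()
    if label == POSITIVE:
        allowed = (sac & ~lum).astype(np.uint8)
        area = int(sac.sum())
        lo = max(4, int(round(config.leak_area_range[0] * area)))
        hi = max(lo + 1, int(round(config.leak_area_range[1] * area)))
        leak_mask = random_blob(allowed, (lo, hi), rng)
        run_lo, run_hi = config.leak_slice_run
        run = int(rng.integers(run_lo, run_hi + 1))
        run = min(run, config.n_slices_per_case)
        start = int(rng.integers(0, config.n_slices_per_case - run + 1))
        leak_slices = set(range(start, start + run))

    case_id = f"ph{case_seed & 0xFFFFFFFF:08x}"
    slices, masks = [], []
    for k in range(config.n_slices_per_case):
        img = rng.normal(config.background_mu, config.background_sigma, (n, n))
        img[sac == 1] = rng.normal(config.sac_mu, config.sac_sigma, int(sac.sum()))
        img[lum == 1] = rng.normal(config.lumen_mu, config.lumen_sigma, int(lum.sum()))
        leak_here = leak_mask if k in leak_slices else None
        if leak_here is not None:
            img[leak_here == 1] = rng.normal(
                config.leak_mu, config.leak_sigma, int(leak_here.sum()))
        if config.noise_sigma > 0:
            img += rng.normal(0.0, config.noise_sigma, (n, n))
        pixels = np.clip(np.round(img), -32768, 32767).astype(np.int16)
        slices.append(CTSlice(pixels=pixels, case_id=case_id, slice_index=k))
        masks.append(MaskSet(
            aneurysm_sac=sac.copy(), stent_lumen=lum.copy(),
            endoleak=(leak_here.copy() if leak_here is not None
                      else np.zeros((n, n), dtype=np.uint8))))
    return CaseRecord(case_id=case_id, slices=slices, masks=masks, label=label)


def generate_cohort(config: PhantomConfig, n_positive: int,
                    n_control: int) -> list[CaseRecord]:
    """Generate a cohort; per-case seeds derive from ``config.seed`` and index."""
    if n_positive < 0 or n_control < 0:
        raise ValueError("cohort counts must be non-negative")
    cases = []
    for i in range(n_positive + n_control):
        label = POSITIVE if i < n_positive else CONTROL
        case_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                        & 0x7FFFFFFF)
        cases.append(generate_case(config, label, case_seed))
    return cases
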