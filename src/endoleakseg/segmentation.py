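"""Compact U-net-style encoder–decoder for per-pixel endoleak probability maps.

The network is symmetric: ``depth`` encoder levels of two 3×3 conv+ReLU layers
followed by 2×2 max-pooling, a bottleneck block, and mirrored decoder levels
of nearest-neighbour upsampling, a 3×3 conv, concatenation with the skip from
the same level, and two more conv+ReLU layers; a 1×1 convolution with sigmoid
gives the probability map.  Channels double per level from ``base_channels``.

Training consumes slices through the endoleak augmentor (add/remove/pass per
slice, then rotation + pixel noise, then clamp/resize/mean-center) and records
per-epoch training loss and validation loss/F1; the snapshot with the best
validation F1 at the 0.5 cut is returned.  Everything runs on the CPU in
float32 and is deterministic under the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .augment import (ADD, NONE, REMOVE, AugmentBatch, IntensityStats, ShapeSpec,
                      augment_batch, estimate_intensity_stats, standard_augment)
from .preprocess import (PreprocessSpec, fit_dataset_stats, preprocess_mask,
                         preprocess_slice)
from .types import CaseRecord

F32 = nn.F32


@dataclass
class ModelConfig:
    """Architecture and optimisation settings for the segmentation network."""

    depth: int = 3
    base_channels: int = 8
    input_size: int = 64
    loss: str = "combined"  # cross_entropy | dice | combined
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}")
        if self.loss not in ("cross_entropy", "dice", "combined"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def dice_weight(self) -> float:
        return {"cross_entropy": 0.0, "dice": 1.0, "combined": 1.0}[self.loss]

    @property
    def bce_weight(self) -> float:
        return {"cross_entropy": 1.0, "dice": 0.0, "combined": 1.0}[self.loss]


@dataclass
class SliceProbMap:
    """Per-pixel endoleak probabilities for one slice, values in [0, 1]."""

    probs: np.ndarray
    case_id: str
    slice_index: int


@dataclass
class AugmentorSettings:
    """How training batches are augmented.

    With the lesion augmentor enabled, each epoch assigns REMOVE to endoleak
    slices with probability p_remove and ADD to sac-bearing slices with
    probability p_add (otherwise NONE).  Rotation/noise augmentation applies
    either way.  Intensity sampling happens in native HU before preprocessing.
    """

    enabled: bool = True
    p_add: float = 0.5
    p_remove: float = 0.5
    shape_spec: ShapeSpec = field(default_factory=ShapeSpec)
    rotation_range_deg: float = 15.0
    noise_sigma: float = 10.0


class UNet:
    """The encoder–decoder network; parameters initialised from config.seed."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        d = config.depth
        self.enc_blocks, self.pools = [], []
        cin = 1
        for i in range(d):
            ci = c * 2 ** i
            self.enc_blocks.append(self._block(cin, ci, rng))
            self.pools.append(nn.MaxPool2())
            cin = ci
        self.bottleneck = self._block(cin, c * 2 ** d, rng)
        self.ups, self.upconvs, self.uprelus, self.dec_blocks = [], [], [], []
        cprev = c * 2 ** d
        for i in reversed(range(d)):
            ci = c * 2 ** i
            self.ups.append(nn.Upsample2())
            self.upconvs.append(nn.Conv2D(cprev, ci, 3, rng))
            self.uprelus.append(nn.ReLU())
            self.dec_blocks.append(self._block(2 * ci, ci, rng))
            cprev = ci
        self.head = nn.Conv2D(cprev, 1, 1, rng)

    @staticmethod
    def _block(cin: int, cout: int, rng) -> list:
        return [nn.Conv2D(cin, cout, 3, rng), nn.ReLU(),
                nn.Conv2D(cout, cout, 3, rng), nn.ReLU()]

    @property
    def layers(self) -> list:
        out = []
        for blk in self.enc_blocks:
            out += blk
        out += self.bottleneck
        for up, uc, ur, blk in zip(self.ups, self.upconvs, self.uprelus,
                                   self.dec_blocks):
            out += [up, uc, ur] + blk
        out.append(self.head)
        return out

    @staticmethod
    def _run(block, h, train):
        for layer in block:
            h = layer.forward(h, train)
        return h

    @staticmethod
    def _back(block, dh):
        for layer in reversed(block):
            dh = layer.backward(dh)
        return dh

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x (N,1,H,W) float32 -> logits (N,1,H,W)."""
        h = x.astype(F32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = self._run(blk, h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self._run(self.bottleneck, h, train)
        self._skip_channels = []
        for up, uc, ur, blk, skip in zip(self.ups, self.upconvs, self.uprelus,
                                         self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = ur.forward(uc.forward(h, train), train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = self._run(blk, h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips = []
        for blk, ur, uc, up, cskip in zip(reversed(self.dec_blocks),
                                          reversed(self.uprelus),
                                          reversed(self.upconvs),
                                          reversed(self.ups),
                                          reversed(self._skip_channels)):
            dh = self._back(blk, dh)
            dskip, dup = dh[:, :cskip], dh[:, cskip:]
            dskips.append(dskip)
            dh = up.backward(uc.backward(ur.backward(dup)))
        dh = self._back(self.bottleneck, dh)
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                    reversed(dskips)):
            dh = pool.backward(dh)
            dh = dh + dskip
            dh = self._back(blk, dh)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, train=False).astype(np.float64))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for _, p, _ in layer.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for _, p, _ in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(flat, weights):
            p[...] = w


def build_model(config: ModelConfig) -> UNet:
    """Construct the network with deterministic initialisation under config.seed."""
    return UNet(config)


def _loss_and_grad(model: UNet, config: ModelConfig, x: np.ndarray, t: np.ndarray,
                   train: bool = True):
    logits = model.forward(x, train=train)
    loss, dz, parts = nn.bce_dice_loss(logits, t, dice_weight=config.dice_weight)
    if config.bce_weight == 0.0:
        # dice-only: recompute without the BCE term
        p = nn.sigmoid(logits.astype(np.float64))
        loss = 1.0 - parts["dice"]
        dz = (dz - (p - t.astype(np.float64)) / p.size).astype(F32)
    return loss, dz, logits


def train_step(model: UNet, optimizer: nn.Adam, config: ModelConfig,
               x: np.ndarray, t: np.ndarray) -> float:
    """One optimisation step on a prepared batch; returns the batch loss."""
    loss, dz, _ = _loss_and_grad(model, config, x, t, train=True)
    model.backward(dz)
    optimizer.step()
    return loss


@dataclass
class TrainedModel:
    """A trained network plus everything inference needs to be self-contained."""

    net: UNet
    config: ModelConfig
    preprocess: PreprocessSpec
    stats: Optional[IntensityStats]
    history: dict

    def predict_case(self, case: CaseRecord) -> list[SliceProbMap]:
        return predict_case(self, case)

    def save(self, directory: str | Path) -> None:
        save_model(self, directory)


def _assign_augment_ids(cases, rng, settings: AugmentorSettings):
    """Per-slice (case_idx, slice_idx, augment_id) for one epoch."""
    items = []
    for ci, case in enumerate(cases):
        for si, ms in enumerate(case.masks):
            lid = NONE
            if settings.enabled:
                if ms.endoleak is not None and ms.endoleak.any():
                    if rng.random() < settings.p_remove:
                        lid = REMOVE
                elif ms.aneurysm_sac is not None and ms.aneurysm_sac.any():
                    if rng.random() < settings.p_add:
                        lid = ADD
            items.append((ci, si, lid))
    return items


def _prepare_batch(cases, items, stats, settings: AugmentorSettings,
                   spec: PreprocessSpec, seed: int):
    """Augment (lesion + standard) and preprocess one batch of slices."""
    slices = [cases[ci].slices[si] for ci, si, _ in items]
    masks = [cases[ci].masks[si] for ci, si, _ in items]
    ids = [lid for _, _, lid in items]
    if any(l != NONE for l in ids):
        res = augment_batch(AugmentBatch(slices, masks, ids), stats,
                            settings.shape_spec, seed=seed)
        xs, ys = res.out_slices, res.out_labels
    else:
        xs = [np.asarray(s.pixels, dtype=np.float64) for s in slices]
        ys = [(m.endoleak if m.endoleak is not None
               else np.zeros(s.shape, dtype=np.uint8))
              for s, m in zip(slices, masks)]
    xb, tb = [], []
    for b, (x, y) in enumerate(zip(xs, ys)):
        sub = int(np.random.SeedSequence([seed, 7, b]).generate_state(1)[0]
                  & 0x7FFFFFFF)
        x, y = standard_augment(x, y, settings.rotation_range_deg,
                                settings.noise_sigma, seed=sub)
        xb.append(preprocess_slice(x, spec))
        tb.append(preprocess_mask(y, spec))
    x_arr = np.stack(xb)[:, None].astype(F32)
    t_arr = np.stack(tb)[:, None].astype(F32)
    return x_arr, t_arr


def _eval_slices(model, config, cases, spec):
    """Validation loss and pixel-level F1 at the 0.5 cut."""
    losses, tp, fp, fn = [], 0, 0, 0
    for case in cases:
        for i in range(0, case.n_slices, config.batch_size):
            chunk = case.slices[i:i + config.batch_size]
            mchunk = case.masks[i:i + config.batch_size]
            x = np.stack([preprocess_slice(s.pixels, spec) for s in chunk])[:, None]
            t = np.stack([preprocess_mask(
                m.endoleak if m.endoleak is not None
                else np.zeros(s.shape, dtype=np.uint8), spec)
                for s, m in zip(chunk, mchunk)])[:, None]
            loss, _, logits = _loss_and_grad(model, config, x.astype(F32),
                                             t.astype(F32), train=False)
            losses.append(loss * x.shape[0])
            pred = nn.sigmoid(logits.astype(np.float64)) >= 0.5
            truth = t.astype(bool)
            tp += int((pred & truth).sum())
            fp += int((pred & ~truth).sum())
            fn += int((~pred & truth).sum())
    n = sum(c.n_slices for c in cases)
    f1 = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return sum(losses) / n, f1


def train(model: UNet, train_cases: Sequence[CaseRecord],
          val_cases: Sequence[CaseRecord],
          augmentor: AugmentorSettings | None = None,
          config: ModelConfig | None = None,
          preprocess_spec: PreprocessSpec | None = None,
          stats: IntensityStats | None = None) -> TrainedModel:
    """Train the network; returns the best-validation-F1 snapshot and history."""
    if not train_cases:
        raise ValueError("empty training set")
    if not val_cases:
        raise ValueError("empty validation set")
    overlap = {c.case_id for c in train_cases} & {c.case_id for c in val_cases}
    if overlap:
        raise ValueError(f"train/val case overlap: {sorted(overlap)}")
    config = config or model.config
    augmentor = augmentor or AugmentorSettings()

    if preprocess_spec is None:
        preprocess_spec = PreprocessSpec(target_size=config.input_size)
    if preprocess_spec.center_mode == "dataset" and preprocess_spec.dataset_mean is None:
        mean, std = fit_dataset_stats(
            (s.pixels for c in train_cases for s in c.slices),
            preprocess_spec.clamp_lo, preprocess_spec.clamp_hi)
        preprocess_spec.dataset_mean = mean
        preprocess_spec.dataset_std = std
    if augmentor.enabled and stats is None:
        stats = estimate_intensity_stats(train_cases)

    optimizer = nn.Adam(model.layers, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_f1": []}
    best_f1, best_weights = -1.0, model.get_weights()

    for epoch in range(config.epochs):
        ep_seed = int(np.random.SeedSequence([config.seed, epoch])
                      .generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(ep_seed)
        items = _assign_augment_ids(train_cases, rng, augmentor)
        order = rng.permutation(len(items))
        ep_losses = []
        for bi, start in enumerate(range(0, len(items), config.batch_size)):
            chunk = [items[j] for j in order[start:start + config.batch_size]]
            b_seed = int(np.random.SeedSequence([config.seed, epoch, bi])
                         .generate_state(1)[0] & 0x7FFFFFFF)
            x, t = _prepare_batch(train_cases, chunk, stats, augmentor,
                                  preprocess_spec, b_seed)
            ep_losses.append(train_step(model, optimizer, config, x, t)
                             * x.shape[0])
        history["train_loss"].append(sum(ep_losses) / len(items))
        vloss, vf1 = _eval_slices(model, config, val_cases, preprocess_spec)
        history["val_loss"].append(vloss)
        history["val_f1"].append(vf1)
        if vf1 > best_f1:
            best_f1, best_weights = vf1, model.get_weights()

    model.set_weights(best_weights)
    return TrainedModel(net=model, config=config, preprocess=preprocess_spec,
                        stats=stats, history=history)


def predict_case(trained: TrainedModel, case: CaseRecord) -> list[SliceProbMap]:
    """One probability map per slice, resized back to the slice's own shape."""
    from .preprocess import resize as _resize

    out = []
    cfg = trained.config
    for i in range(0, case.n_slices, cfg.batch_size):
        chunk = case.slices[i:i + cfg.batch_size]
        x = np.stack([preprocess_slice(s.pixels, trained.preprocess)
                      for s in chunk])[:, None].astype(F32)
        probs = trained.net.predict_proba(x)[:, 0]
        for s, p in zip(chunk, probs):
            if p.shape != s.shape:
                p = np.clip(_resize(p, s.shape[0], kind="image"), 0.0, 1.0)
            out.append(SliceProbMap(probs=p, case_id=case.case_id,
                                    slice_index=s.slice_index))
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(trained.net.get_weights())})
    meta = {
        "model_config": asdict(trained.config),
        "preprocess": asdict(trained.preprocess),
        "intensity_stats": trained.stats.to_dict() if trained.stats else None,
        "history": trained.history,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    config = ModelConfig(**meta["model_config"])
    net = UNet(config)
    with np.load(directory / "weights.npz") as z:
        net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    stats = (IntensityStats.from_dict(meta["intensity_stats"])
             if meta["intensity_stats"] else None)
    return TrainedModel(net=net, config=config,
                        preprocess=PreprocessSpec(**meta["preprocess"]),
                        stats=stats, history=meta["history"])
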