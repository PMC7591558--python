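# Methods

## Problem and approach

After endovascular aortic repair (EVAR), an endoleak — persistent flow outside
the stent graft but inside the aneurysm sac — appears on CT angiography (CTA)
as a contrast-bright region within the mostly thrombosed, mid-intensity sac.
`endoleakseg` detects endoleaks from slice stacks in three stages: a compact
encoder–decoder network predicts a per-pixel endoleak probability map for each
slice; a decision stage converts maps into per-slice calls (probability
threshold plus component-size filtering) and aggregates them into one
per-case diagnosis; and, during training, a lesion-aware augmentor
manufactures paired positive/negative examples so the network learns the
lesion rather than incidental anatomy.

## The lesion augmentor

The augmentor rests on a simple statistical model: endoleak pixels and sac
thrombus pixels are each approximately Gaussian in HU. Both Gaussians are fit
by pooling all labeled pixels across the training cases — endoleak pixels
give (u_e, σ_e); sac pixels, excluding the stent lumen and any labeled
endoleak, give (u_a, σ_a). Pooling globally rather than per slice keeps the
estimates stable when labeled slices are few.

Two operations then act on a slice in native HU, before any clamping or
centering:

* **add** — a random-shaped blob is drawn inside the aneurysm-sac mask
  (excluding the stent lumen by default, since an endoleak is extra-graft by
  definition) and filled with independent N(u_e, σ_e²) draws; the blob
  becomes the new training target.
* **remove** — the pixels under the endoleak mask are replaced with
  independent N(u_a, σ_a²) draws and the target becomes empty.

Pixels outside the blob/mask are never touched, so removing a lesion and
re-inserting one at the same location yields an anatomically identical pair
differing only in the lesion. Draws are independent per pixel — no spatial
texture is synthesised; an edge-feathering radius could be added for realism
experiments but defaults to off (radius 0 ≡ not applied).

Random blob shapes are unions of 2–5 random ellipses anchored inside the
allowed region, intersected with it, smoothed by morphological closing
(radius 1), and rejection-sampled until a single 4-connected component with
area in the requested range results (default 5–25% of the allowed region's
area). Each batch element derives its own seed from the master seed and its
index, so augmentation is reproducible end to end.

During training, each epoch assigns REMOVE to endoleak-bearing slices with
probability 0.5 and ADD to lesion-free sac-bearing slices with probability
0.5, otherwise no lesion augmentation; the mixing ratio is a package choice,
as is the standard augmentation applied afterwards (rotation uniform in
±15°, additive zero-mean pixel noise of 10 HU).

## Preprocessing

Raw HU values are clamped to [−1024, 1024] (a typical CTA display range),
resized to the model's input resolution (bilinear for images,
nearest-neighbour for masks so they stay binary; lumen masks are
re-intersected with sac masks after independent resizing), mean-centered and
scaled to unit variance. The mean and SD default to dataset statistics
estimated on training slices only — both are persisted with the model so
inference is self-contained and the test set never leaks into them; a
per-slice variant uses each slice's own mean/SD. Unit-scale inputs matter in
practice: feeding raw-HU offsets (magnitudes of hundreds) into the
He-initialised network saturates early training and makes convergence
luck-dependent, whereas standardised inputs train reliably across seeds.

## Network and training

The network is a small U-net-style encoder–decoder: `depth` levels of two
3×3 conv + ReLU layers and 2×2 max-pooling, a bottleneck block, and mirrored
decoder levels of nearest-neighbour upsampling, a 3×3 conv, skip
concatenation and two conv + ReLU layers, closed by a 1×1 conv with sigmoid.
Channels double per level from `base_channels`. It is implemented directly
on numpy (im2col convolutions lowered to BLAS matrix products, hand-written
backward passes, Adam) in float32; this keeps the package dependency-light,
fully deterministic under its seeds, and fast enough for desk-scale inputs.

The loss is binary cross-entropy plus a soft-Dice term computed over the
whole batch (ε = 1 smoothing keeps it defined for all-background targets);
cross-entropy-only and Dice-only variants are configurable. Defaults:
depth 3, base 8 channels, 64×64 input, batch 16, Adam at 1e-3 (the canned
experiment uses 3e-3 for 10 epochs). After each epoch the validation loss
and pixel-level F1 at the 0.5 cut are recorded; the snapshot with the best
validation F1 is kept.

## Decision stage

The operating probability threshold is chosen on the validation set by
scanning a grid (0.10–0.90, step 0.05) and maximising slice-level F1, where a
slice is predicted positive iff any pixel reaches the threshold and truly
positive iff its endoleak mask is non-empty. Maximising precision, recall
and F1 simultaneously is not possible in general; F1 is the harmonic
compromise, and the precision/recall achieved at the chosen point are
reported alongside. Ties break toward the higher (more specific) threshold.

Binarised maps are cleaned by removing 4-connected components with area
outside inclusive bounds (defaults 10 px to 20% of a 64² image, per
component per slice); a slice is called positive iff any pixel survives. A
case is called positive when positive slices form a run of `case_k`
consecutive slice indices (default rule) or number at least `case_k` in
total (alternative rule). The default `case_k` is 2: a real endoleak should
persist across adjacent slices, and the synthetic lesions span at least two,
so k = 2 detects the minimal lesion while suppressing isolated single-slice
false positives.

For slice-level ROC analysis the continuous slice score is the maximum
probability inside surviving components (0 when nothing survives);
mean-of-top-k could be substituted. AUC is trapezoidal over all score cuts,
identical to the pairwise-concordance statistic with ties counted half.
Case-level uncertainty is the SD of accuracy over bootstrap resamples of
whole cases with replacement (default B = 1000).

## Synthetic phantom cohorts

The phantom generator makes every stage testable without patient data. Each
case is a short stack (default 6 slices of 64×64 px) containing an elliptical
aneurysm sac (40±12 HU), a circular stent lumen inside it (250±25 HU), a
background of 0±15 HU, and — in positive cases — a random blob of 180±25 HU
occupying 2–15% of the sac area on a contiguous run of 2–5 slices, placed
inside the sac but outside the lumen. Zero-mean Gaussian noise (10 HU) is
added everywhere and pixels are rounded to integer HU (int16), as CT data are
stored. The palette is a plausible CTA-like convention chosen for clear
contrast ordering (lumen > leak > sac > background), not a claim about any
specific scanner. Because noise is additive, the observed SD of a region is
√(σ_region² + σ_noise²); `PhantomConfig.effective_sigma` exposes this and is
the reference for parameter-recovery checks.

What the phantom does *not* emulate: organs, bone, stent-metal artifacts,
partial-volume effects, spatially correlated noise, multi-phase contrast
dynamics, or anatomical variability between slices of a case. Tests passing
on phantoms therefore demonstrate the pipeline's correctness and the
augmentor's statistical fidelity, not clinical performance on real CTAs.

## Canned experiment and problem sizes

`endoleakseg.experiments.run_phantom_experiment` reproduces the study design
at desk scale: a 70-case cohort (50 positive, 20 control), stratified split
of 32+8 / 8+2 / 10+10 cases (train/validation/test, positive+control),
training through the augmentor, threshold selection on validation, and
evaluation on the held-out 20 cases (slice-level AUC over 120 slices,
case-level accuracy/precision/recall, bootstrap SD). Problem sizes — 64×64
slices, 6 slices per case, depth-3 base-8 network, 10 epochs at learning
rate 3e-3 — were chosen so a full experiment runs in about two minutes on a
single CPU core. The ablation arm disables lesion add/remove (rotation and
noise augmentation remain), trains on the phantoms' native lesions only, and
is compared on mean case accuracy.

## Numerical choices and edge cases

* Clamping is exact and idempotent; mask resizing thresholds at 0.5 and can
  only produce {0, 1}.
* Gaussian sampling uses numpy `default_rng` streams; every nested stage
  (case, epoch, batch, element) derives its seed from the master seed via
  `SeedSequence`, so all outputs are bit-reproducible on one machine.
* σ = 0 intensity models degenerate to constant fills, exactly.
* An empty endoleak mask passed to the remover is a warned no-op rather than
  an error, so mixed batches need no special-casing upstream.
* Undefined metric ratios (e.g. precision with no positive calls) are
  reported as NaN, never silently as 0.
* The remover/adder return float64 slices; stored cohorts quantise to int16.

## Known limitations

* Independent per-pixel draws give inserted lesions a slightly "salty"
  texture compared with real endoleaks; a human reader would not be fooled,
  but the segmentation statistics the pipeline relies on are preserved.
* The case-level rule assumes consistent slice spacing; `case_k` should be
  rescaled for thin-slice acquisitions.
* The CPU network is small; scaling to 512² clinical resolution would need a
  GPU-backed implementation behind the same interfaces.
* DICOM reading assumes one series per directory and uses the standard
  slope/intercept rescale only.
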