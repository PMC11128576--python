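# Methods

## Problem

Multimodal medical fusion images (MMFI) merge a structural scan (CT/MRI) with
a functional one (PET/SPECT). Different fusion algorithms produce images of
very uneven quality, and in the clinic there is no pristine reference to
compare against, so quality must be assessed *blind*. The supervision signal
is the radiologist mean opinion score (MOS) on a 1–5 scale; a predicted score
is judged by how well it correlates with MOS over a held-out set (PLCC,
SRCC, KRCC) and by its RMSE on the MOS scale.

## Model

The package implements a GAN-guided nuance-perceptual attention network:

1. **Generator G** maps a fused image of arbitrary quality `I_org` to an
   estimate of the best-quality fusion of the same scene,
   `I_hq = G(I_org)`. Architecture: three down-sampling blocks
   (3×3 conv → LeakyReLU(0.2) → BN → residual block of three 3×3 convs with a
   skip), stride 2 while the resolution is above one quarter of the input
   (for 128×128 inputs the encoder visits 64 and 32); then five **Unique
   Feature Warehouse (UFW)** blocks at quarter resolution; then a four-layer
   decoder (upsample ×2 in the first two layers; 3×3 conv → BN → LeakyReLU,
   Sigmoid in the last layer). A UFW block processes its input at three
   scales (full, 1/2, 1/4 via average pooling), each through a
   3×3 conv → LeakyReLU → BN branch, upsamples the coarser branches back,
   concatenates the branches along channels, merges with a 3×3 conv, and adds
   a skip from the block input. `G` is trained with
   `L_G = log(1 − D(G(I_org))) + θ·MSE(G(I_org), I_GT)`, where `I_GT` is the
   highest-MOS image of the group and θ = 0.5.
2. **Discriminator D**: four 3×3/stride-2/pad-1 conv layers
   (LeakyReLU → BN), each halving both spatial dimensions
   (128→64→32→16→8), then an independent classifier conv, global average
   pooling and a sigmoid. Its objective (maximized) is quality-weighted:
   `mean log D(I_GT) + mean log(1 − |D(G(I_org)) − W|)` with a per-sample
   binary weight `W = 1` iff the quality network scores the generated image
   at MOS ≥ 3 (the diagnostically safe regime). Where `W = 0` the fake term
   is exactly the plain GAN term `log(1 − D)`; where `W = 1` it becomes
   `log D`, i.e. generated images that already clear the diagnostic bar are
   pushed toward the "real" label and the adversarial pressure on them is
   lifted.
3. **Attention quality network (AQA)**: the nuance map
   `I_sub = |I_hq − I_org|` and `I_org` each pass a separate stem conv, are
   concatenated and traverse a VGG11-style trunk (eight 3×3 convs; max-pools
   at the standard VGG positions, applied while the spatial size is above the
   4×4 CAM resolution — five pools for 128×128 inputs, three for 32×32). The
   trunk's globally pooled features are concatenated with the channel-wise
   global average of `F_last` (the generator's last UFW map) and fed through
   two fully connected layers to a raw score `Q_pre`; `σ(Q_pre)` is trained
   with a continuous-target binary cross entropy against the normalized MOS
   `(MOS−1)/4`. A class activation map over the last conv features — using
   the composite head weights as the cue — is min-max normalized and
   supervised with an L1 loss (weight φ = 1) against a ground-truth attention
   map. The total objective couples the parts with weight γ = 0.01 on the
   quality-network loss evaluated on generated images, so the generator must
   satisfy the quality network as well as the discriminator.

Training uses Adam (initial learning rate 2·10⁻⁴, decayed by 0.95 every 20
batches), grouped five-fold cross-validation (source pairs, never single
images, are assigned to folds), per-epoch validation, and best-checkpoint
selection by validation SRCC.

## Design choices where the design was open

* **Tensor engine.** All networks run on a small reverse-mode autograd engine
  (`g2npan.nn`) over numpy float32 arrays: im2col convolutions executed as
  batched BLAS matmuls, explicit backward closures, finite-difference-checked
  gradients. Checkpoints are plain `.npz` archives.
* **Channel widths** (unspecified upstream): encoder 3→32→64→64, UFW at 64,
  decoder 64→64→32→16→3, discriminator 3→32→64→128→256, VGG11 trunk scaled by
  `base_width/64`. All widths are configuration fields; the desk-scale
  defaults used in tests shrink them ~4–8×.
* **Decoder layer count vs. resolution.** Four decoder layers but only a 4×
  spatial gap: layers 1–2 upsample, layers 3–4 refine at full resolution.
* **Discriminator input.** A single image (the figure's single-input CNN and
  the discriminator objective agree on this); a conditional,
  channel-concatenated variant sits behind `DiscriminatorConfig.conditional`.
* **CAM cue with a two-layer head.** The classical CAM uses the weights of a
  single FC layer from pooled channels to the output. With the two-layer head
  the composite linear map `W2·W1`, restricted to the spatially resolved
  trunk channels (the pooled `F_last` entries are excluded), plays that role.
  A constant raw map normalizes to all zeros.
* **CAM ground truth.** In the synthetic pipeline the known per-pixel
  distortion-severity map, block-mean downsampled to CAM resolution and
  min-max normalized, serves as `F_GT`. For data without severity maps the
  CAM loss is disabled.
* **Feature fusion in the head.** `F_last` (quarter-resolution, generator
  channels) cannot be concatenated with the 4×4 trunk features directly;
  channel-wise global average pooling of both, then vector concatenation,
  resolves the resolution mismatch.
* **Quality feedback term.** The coupling loss on generated images is taken
  to be the quality network's own objective evaluated on
  `(I_org, |I_hq − I_org|, F_last)` with gradients flowing into `G` — the
  generated image must remain useful to the assessor.
* **Update scheme.** Each batch runs a discriminator ascent step followed by
  a combined generator/quality step: since the generator objective already
  contains `γ·L_R` and `L_R` *is* the quality objective, one shared
  forward/backward serves both networks (the quality network's gradients are
  the deposited ones rescaled by 1/γ — exact at the pre-update point). This
  is the simultaneous-update variant of GAN training; the nuance the quality
  network learns from is at most one optimizer step stale, which avoids the
  instability that epoch-stale nuance would cause. When the quality feedback
  is disabled (ablation rungs), the quality network takes its own separate
  step on the detached nuance.
* **Perceptual weight of generated images.** `W` is recomputed every batch
  from the current quality network's score of `I_hq`, with a zero nuance map
  (the generated image is its own best-quality version) and the current
  `F_last`.
* **Repeated evaluation.** Validation metrics can be averaged over repeated
  80% resamples of the test images (`eval_repeats`, default 10) to emulate
  repeated-evaluation averaging; per-epoch model selection uses a single
  pass.
* **Numerical safety.** Sigmoid outputs are clamped to
  `[10⁻⁶, 1−10⁻⁶]` (float32 saturates exactly otherwise) and every log is
  epsilon-clamped at 10⁻⁷. Non-finite losses abort with the offending
  component named. Batches of size 1 are skipped (batch norm needs ≥ 2
  samples).

## Synthetic data generator

Real MMFI quality databases (groups of ~10 fusion-algorithm outputs per
source pair, radiologist MOS, highest-MOS image as the group reference) are
private. The generator emulates their *structure*:

* a **structural** source image: piecewise-smooth random ellipses/rectangles
  with sharp edges plus mild smooth texture;
* a **functional** source image: a low-frequency blob field concentrated in a
  random lesion region, given a hot-metal tint in color groups (grayscale
  groups are replicated to three channels, mirroring the mixed color/gray
  composition of such databases — default 129 groups of which 9 grayscale);
* per group, ten variants: the clean weighted fusion degraded by a
  severity-scaled bank of blur (σ = 2.5·s), additive Gaussian noise
  (sd 0.06·s), modality-weight imbalance (±0.35·s), and extra smoothing
  inside a random patch (recorded at 1.5·s in the per-pixel severity map);
  severity 0 reproduces the clean fusion exactly;
* MOS = 5 − 4·severity, optionally with bounded rater noise (off by
  default), so the within-group MOS ranking is exactly the inverse severity
  ranking and ranking recovery is testable;
* the highest-MOS variant is the group reference; ties (possible only with
  rater noise) are broken uniformly under a seed.

Everything is a pure function of (config, seed). What the generator does
**not** emulate: anatomy, real fusion-algorithm failure modes (halo,
ghosting, color distortion of specific algorithms), rater disagreement
structure, or any relationship between image content and score beyond the
injected severities. A model that passes the synthetic tests has demonstrated
that the architecture and training loop can recover a known monotone
quality signal — not clinical validity.

* **Learning-rate decay interval at desk scale.** The ×0.95-every-20-batches
  schedule presumes full-scale epochs of a hundred-plus batches; a desk epoch
  has ~15, so the literal interval drives the learning rate to ~10⁻⁷ of its
  initial value within 40 desk epochs and freezes training long before the
  protocol ends. The desk protocol therefore decays every 150 batches
  (~10 desk epochs), preserving the multiplicative-staircase form; the
  full-scale default remains 20.

## Desk-scale study conditions

CPU-sized runs used by the tests and the acceptance script: 30 groups × 10
variants at 32×32 resolution, grouped 24/6 train/test split, 200 epochs,
batch 16, generator base width 8 (UFW at 16 channels, 8×8), discriminator
widths (8, 16, 32, 32), trunk base width 8, head width 32. The ablation
comparison (full model vs trunk-only baseline) and the train-fraction sweep
(20% vs 80%) run 40 epochs on 16- and 15-group datasets over three seeds.
The full-resolution 128×128 architecture is exercised by the shape-contract
tests; training at that scale follows the same code paths.

## Known limitations

* **The synthetic benchmark understates the value of reference
  hallucination.** In the synthetic bank, severity is carried mostly by
  distortions that are directly visible in the image (blur, additive noise),
  so the bare quality trunk already ranks held-out images near-perfectly
  (SRCC ≈ 0.9 at desk scale) and the GAN/nuance machinery — whose advantage
  on real radiologist-scored data rests on quality aspects that require
  reference information — mainly adds optimization noise there: the full
  model reaches SRCC ≈ 0.7–0.8 on the same folds. The ablation-ordering
  test therefore fails on synthetic data; its outcome there says little
  about the ordering on real fusion databases.

* The engine is single-threaded numpy; training beyond desk scale is slow.
* `use_pretrained_trunk` exists as an opt-in hook (`pretrained_path`) but no
  weights ship with the package; the default is random initialization.
* With rater noise enabled the severity→MOS map is no longer strictly
  monotone, and the reference can be a tied draw; the learning tests keep
  noise off.
* Kendall's tau-b and average-rank Spearman are the tie conventions; other
  harnesses sometimes use tau-a or competition ranks.
* PLCC is computed without a logistic remapping by default
  (`logistic_remap=True` enables the 4-parameter fit).
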