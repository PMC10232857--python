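# Methods

## Problem and model

Multi-site studies of white-matter lesions (the motivating case is
multiple sclerosis on FLAIR MRI) cannot always pool raw images, so a
segmentation model is trained federatedly: each site ("client") trains
locally and only model parameters travel to a central server, which
aggregates and redistributes them. Two kinds of inter-site heterogeneity
break the naive protocol:

* **domain shift** — scanner- and protocol-dependent intensity, contrast
  and noise differences between sites;
* **label shift** — sites differ systematically in lesion burden; a site
  whose patients carry few, small lesions contributes weak gradients and
  is poorly served by a uniformly aggregated model.

The framework in this package addresses both with re-weighting, on top
of a normalization-preserving federated baseline.

**Local objective.** Each client *i* minimises the soft Dice loss for
probabilistic binary segmentation,

```
L_dice = 1 − (2 Σ p·y + ε) / (Σ p² + Σ y² + ε),
```

with voxelwise predicted probabilities *p*, binary labels *y*, and a
smoothing constant ε = 1e-5 in numerator and denominator (so a perfect
binary prediction scores exactly 0 and an empty/empty pair is defined
and scores 0; without ε the loss is undefined on lesion-free patches).

**Parameter partition (FedBN baseline).** The model parameters split
into θ = {θ^bn, θ^r}: everything belonging to batch-normalization
layers — affine weight and bias *and* the running mean/variance
buffers — versus the rest. The server aggregates only θ^r; θ^bn never
leaves the client, on the premise that normalization state encodes the
site-specific intensity distribution. Running statistics are
deliberately part of θ^bn: they are pure data statistics of the local
domain.

**Ability-weighted aggregation (CA mechanism).** Per training
iteration, each client measures its segmentation ability

```
P = (Σ p·y / Σ y) · (1 − L_dice),
```

i.e. the mean predicted probability on true-lesion voxels (confidence
restricted to true positives — lesions occupy ~1% of the brain, so
whole-image confidence is uninformative) times the achieved Dice
overlap. The round mean of P becomes the client's aggregation weight:

```
θ̂^r = Σ_i P_i θ_i^r / Σ_i P_i.
```

An iteration whose ground-truth patch has no lesion voxels yields no
observation (the score is undefined there); if a client's entire round
is lesion-free its ability is reported absent and the server substitutes
the mean ability of the reporting clients (0.5 if none report).

**Lesion-volume loss re-weighting (LT mechanism).** Each client tracks
the lesion-volume ratio of its training patches — lesion voxels over
brain voxels, where brain = nonzero-intensity support (patch-relative,
so patches that clip the brain boundary are not under-counted) — as a
running mean vr_i across rounds. From round 2 on the client's loss is
scaled by

```
w_i = (Σ_j vr_j) / (N · vr_i),
```

so low-burden clients train with proportionally larger steps. The factor
is clipped to [0.1, 10] with a 1e-6 floor on vr_i; the raw formula is
undefined for lesion-free clients. Round 1 uses w_i = 1 (no ratios have
been observed yet). Note Σ_i w_i·vr_i = Σ_i vr_i whenever the clip is
inactive.

**Ablation variants.** `ours_ent` replaces the true-positive confidence
with the mean prediction-entropy map, P^e = mean(−p·log p)·(1−L_dice);
`ours_vol` drives the loss weight with raw lesion voxel counts v_i
instead of ratios. Both are implemented as modes; both are known to be
less robust than the ratio/confidence forms.

**Baselines.** `fedavg` (uniform mean of *all* parameters), `fedprox`
(fedavg plus a proximal penalty μ/2·‖θ−θ_start‖², standard form, μ
configurable, default 1e-3), `fedbn`, and the two single-mechanism
ablations `fedmsrw_ca_only` / `fedmsrw_lt_only`.

## Training protocol

Algorithmically, for rounds p = 1..P: every client is initialised from
the redistributed global model (full parameters in fedavg/fedprox;
shared parameters only in the bn-local modes), computes its loss weight
from the ratios accumulated through round p−1, trains Q iterations of
SGD, reports (θ_i, round-mean P_i, round-mean ratio) to the server,
which aggregates and redistributes. Defaults mirror full-scale practice
for this task: SGD momentum 0.9, weight decay 5e-4, learning rate 2e-4,
Q = 800. Momentum buffers are client-local and persist across rounds;
they are never transmitted (the protocol is silent on this; keeping them
local avoids sending twice the payload). Client order in every
aggregation sum is fixed (sorted client id) so floating-point summation
is reproducible; all randomness is derived from a single master seed via
per-(client, round) seed sequences, so changing one client's data or the
mode never perturbs another client's sampling stream.

**Privacy contract.** Only parameters and two scalars per round
(ability, mean lesion-volume ratio) reach the server. Raw volumes,
masks, and normalization statistics never leave the client.

**Numerical reductions.** With abilities forced uniform and loss weights
forced to 1, `fedmsrw` executes bit-identically to `fedbn`; `fedprox`
with μ = 0 is bit-identical to `fedavg`; equal-ability weighted
aggregation is bit-identical to plain averaging (both paths share one
accumulation routine). These identities are exercised in the test suite.

## Network

A small configurable 3-D encoder–decoder (U-Net-like): per level one
conv(3³)–BatchNorm–ReLU block followed by 2³ max-pooling; a bottleneck
block; decoder levels with nearest-neighbour 2× upsampling, skip
concatenation and a conv block; a 1³ conv head with sigmoid output.
Rotating through `base_channels · 2^level` channels. Input patch axes
must be divisible by 2^depth. The head bias is initialised to −2 so
initial probabilities start near 0.12, which avoids the flat-gradient
cold start of the Dice loss on sparse targets. All layers carry explicit
forward/backward passes in numpy (im2col + BLAS matrix products);
gradients are verified against finite differences in the tests. The
network is deliberately tiny (10⁴–10⁵ parameters at the settings used
here) so that a full federation runs on one CPU in about a minute;
nothing about the aggregation mechanics depends on network scale.

## Inference

Full volumes are tiled with network-sized patches; offsets advance by a
configurable stride (default patch/2) with the final offset clamped to
the far edge, so every voxel is covered by at least one fully-inside
patch. Probabilities are averaged over covering patches and thresholded
at 0.5. Volumes smaller than the patch are zero-padded and cropped back.
Normalization layers run in evaluation mode, using the client's private
running statistics.

**Batch-norm recalibration.** The last thing a federation does is a
client-local recalibration pass: because the server moves the shared
weights *after* the final local training pass, the running BN statistics
each client accumulated during training describe the pre-aggregation
activations and can be badly stale for the assembled final model — at
desk scale this intermittently collapsed held-out Dice in every mode.
Each client therefore refreshes its running statistics with
`bn_recal_batches` (default 25) forward passes over its own training
patches before evaluation. This is a pure inference-side fix: it
involves no labels, no gradient steps and no communication, and is
applied identically in every mode.

## Synthetic phantoms

The generator emulates a multi-site lesion study at toy scale. Per
client: an axis-aligned ellipsoidal "brain" (fraction `brain_radius_frac`
of the half-extent) filled with a smooth positive texture (1 + four
random low-frequency 3-D cosines, amplitudes 0.08–0.2) at mean tissue
intensity 100; spherical lesions hyperintense by +40% of local tissue;
then the client's domain shift is applied — multiplicative
`intensity_scale`, additive `intensity_offset`, Gaussian noise of
`noise_sigma` inside the brain — and the background is exactly zero
(brain-extracted convention). Lesion count is drawn by stochastic
rounding of a mean (floor + Bernoulli of the fraction): the draw has
exactly the requested mean, is degenerate at integer means, and never
yields zero lesions once the calibrated mean is ≥ 1. The mean is
calibrated at profile construction so that the expected lesion-to-brain
volume ratio equals `target_ratio`, using the *digitised* sphere volume
averaged over the radius range (small digitised spheres deviate strongly
from 4πr³/3); profiles whose target is unreachable (calibrated mean
< 1) are rejected at construction unless empty cases are explicitly
allowed. Lesion centres are drawn inside the ellipsoid eroded by the
lesion radius, with bounded retries and a hard error naming the profile
if placement fails.

Training patches are uniform random crops with optional augmentation
from the 90°-rotation/flip orthogonal group only — no interpolation, so
masks stay binary and voxel multisets are preserved.

What the phantoms deliberately do **not** model: registration artifacts,
bias fields, partial-volume effects, anatomically shaped lesions
(periventricular distribution, confluence), multi-modal MR physics.
Passing the end-to-end tests shows the federated mechanics behave as
specified under controlled domain/label shift; it is not evidence of
segmentation accuracy on real MRI.

## Desk-scale benchmark (`fedmsrw.scenarios`)

The reference scenario used by the acceptance checks: two clients, eight
24³ cases each (six train / two held out), lesion-burden targets 0.01 vs
0.04, intensity offsets 0 vs +50 (vs tissue mean 100), noise σ = 2;
depth-2, base-8 network (~47k parameters); 5 rounds × 50 iterations,
batch 4, patch 16³, learning rate 1e-2. The full-scale default of 2e-4
is kept as the config default but makes no visible progress within 250 iterations
at this scale; 1e-2 was chosen by watching single-client training-loss
convergence on the phantom task. One federation takes about a minute on
one CPU.

## Numerical choices and edge cases

* Metric conventions at zero denominators: Dice = 1 when TP=FP=FN=0,
  TPR = 1 when TP+FN=0, FPR = 0 when TP+FP=0.
* The reported "FPR" is FP/(TP+FP) — the false-discovery rate — kept in
  that form for comparability with published multi-site lesion
  segmentation tables; it is not FP/(FP+TN).
* Metrics are reported in percent; C-Dice averages per-case Dice scores,
  the V-metrics pool voxel counts over all cases first.
* Binarisation threshold for case-level evaluation is 0.5.
* Ability for aggregation uses the current round's mean only; no
  cross-round smoothing.
* Aggregation accumulates in float64 and stores float32.
* Running lesion-volume ratios are kept in float64; after k rounds the
  running value equals the arithmetic mean of the k round means to
  1e-12.
* Cross-validation folds are shuffled within client and dealt
  round-robin (sizes differ by at most one); V-metrics pool counts
  across folds, per-fold values are also logged.

## Known limitations

* Single-process simulation only: no real networking, stragglers,
  asynchrony or secure aggregation.
* The phantom task is far easier than clinical MS segmentation; absolute
  Dice values here do not transfer.
* One scalar ability per client per round (no per-layer weighting).
* The numpy network is CPU-bound and small; it is not a performance
  implementation, and architecture fidelity beyond "3-D encoder–decoder
  with batch norm" is not claimed.
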