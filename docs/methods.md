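# Methods

`fedusim` is a desk-scale simulation of federated learning (FL) with
client-side differential privacy (DP) for breast-ultrasound lesion
classification. Every mechanism of the full-scale setting — synthetic
class-structured images, heterogeneous client partitioning, three aggregation
algorithms, per-sample-clipped noisy local training, closed-form privacy
accounting, and the evaluation/ablation machinery — is implemented and
exercised on one CPU in minutes, using small exact-gradient classifiers in
place of large ImageNet networks.

## Synthetic image model

Images are grayscale phantoms in [0,1], square (default 64×64; 224×224 is
accepted through configuration):

* **Background**: a smooth Gaussian-filtered random field (amplitude 0.10
  around a base intensity of 0.55) modulated by multiplicative folded-normal
  speckle, |N(1, s)| with `speckle_strength` s = 0.35. Folded-normal
  multiplicative noise is the standard first-order caricature of ultrasound
  speckle texture.
* **Benign lesion**: a hypoechoic ellipse (interior intensity multiplied by
  `lesion_contrast` = 0.45) with semi-axes drawn from 0.12–0.22 of the image
  side, random orientation and a smooth anti-aliased margin (~2 px sigmoid
  edge).
* **Malignant lesion**: the same ellipse family, but the boundary radius is
  modulated by radial spicules (8–14 angular lobes, relative amplitude 0.25),
  the margin is sharper (~0.8 px), and a faint posterior shadow band
  (strength 0.12) darkens the columns beneath the lesion.

The two lesion classes deliberately share their size, depth and contrast
distributions. Lesion *presence* is then a large, salient intensity cue while
benign-vs-malignant hinges on margin irregularity that survives neither
mean-pooling nor a linear decision boundary well. This reproduces the
difficulty ordering of the real problem — screening (normal/abnormal) is far
easier than diagnosis (benign/malignant) — without claiming clinical realism.
On defaults, a 5-fold logistic reference classifier on 8×8 pooled features
scores roughly 0.90 on screening vs roughly 0.60 on diagnosis.

What the generator does **not** emulate: acoustic physics, scanner-specific
artifacts, patient identity (so no patient-level split disjointness),
annotation noise, or class-conditional appearance beyond the two geometric
cues. Passing tests therefore demonstrate that the *pipeline mechanics* and
*relative orderings* behave correctly, not that any accuracy transfers to
real ultrasound data.

### Default study conditions

Class counts default to 400/520/280 (normal/benign/malignant, N=1,200),
mirroring the 33/43/23 class mix of the emulated corpus at desk scale. The
split is image-level 80/10/10 with the test block drawn first from the seeded
permutation, so every configuration sharing a seed holds out the identical
global test set. Split counts are round-half-even of fraction·N (at
N=15,847 the test set has 1,585 images).

## Preprocessing

Chain (in order): bicubic resize → CLAHE → 3×3 Gaussian noise reduction →
standardization with the fixed ImageNet statistics. Numerical choices:

* CLAHE uses an 8×8 tile grid; the OpenCV-style clip limit 2.0 is mapped to
  scikit-image's normalized limit as 2.0/256 (256 histogram bins). A constant
  image bypasses equalization (it is the identity there and avoids a 0/0).
* The Gaussian kernel is specified by its 3×3 support; sigma follows the
  common kernel-to-sigma rule sigma = 0.8, with the filter radius set to
  kernel//2.
* Standardization default is single-channel using the mean of the ImageNet
  channel means/sds (0.449/0.226); `replicate` mode produces a 3-channel
  array standardized per channel for consumers that want the RGB convention.
  The desk-scale models are single-channel, so `single` is the default.

Each stage's output mean/sd is recorded on the sample for audit; a non-finite
intermediate raises an error naming the stage.

## Client partitioning

IID mode deals each class round-robin (sizes within 1, class mix as close to
global as rounding permits). Non-IID mode composes, in order:

1. **Label skew** — each of K=8 clients draws class proportions from
   Dir(α·p), α = 0.5, p the global class distribution. Integerization: each
   class pool is divided across clients by largest-remainder rounding of the
   drawn proportions and filled by sampling without replacement. This
   guarantees an exact partition (disjoint, exhaustive) for every draw; a
   draw leaving a client empty is redrawn (up to 100 attempts) unless
   explicitly permitted.
2. **Quantity skew** — each client's size is multiplied by an independent
   LogNormal(0, sd) factor (sd = 0.5) and the targets rescaled to conserve
   the training total, the largest client absorbing the rounding residue.
   Multiplicative factors (rather than a fresh size draw) make sd = 0 exactly
   the identity. Samples are re-allocated from per-class pools preserving
   each client's class mix as closely as the integer targets allow; the last
   client takes the remainder, which conserves the total exactly.
3. **Feature skew** — one fixed (brightness, contrast, rotation) draw per
   client, a pure function of (client_id, seed), applied lazily at image-load
   time so stored pixels stay canonical. Default ranges: ±0.2 brightness,
   0.8–1.2 contrast, ±15° rotation.

The published 8-client reference table ships as a static fixture: it is one
unreported-seed realization and cannot be regenerated, so totals and
percentages are transcribed and integer counts reconstructed once by
largest-remainder (the reconstruction rounds back to every printed
one-decimal percentage). Note the printed per-client percentages do not
aggregate exactly to the printed global class mix; the fixture reproduces the
per-client rows and totals, which are what the integrity checks assert.

## Models

Two families behind one flat parameter-vector contract: multinomial logistic
regression (zero-initialized) and a one-hidden-layer tanh network (symmetric
uniform init, scale 0.1). Cross-entropy gradients are closed form and
computed per sample, so DP clipping needs no autodiff. Images enter the
classifier as grid×grid block means (default 8×8 → 64 features), z-scored
with training-set statistics.

The communication-cost model is 2 × |θ| × 4 bytes × K (one upload plus one
download of 32-bit parameters per participating client), reported in MB with
1 MB = 10⁶ bytes. The seven reference architectures are packaged as a
(name, parameter-count) table feeding this model.

## Federation

Per round: broadcast → E local epochs of mini-batch descent per client →
aggregate. Local epochs visit ⌊n/B⌋ full batches (trailing partial batch
dropped; a client smaller than one batch errors unless a flag permits a
single undersized batch). The client learning rate (default 10⁻³) decays by
0.1 from rounds 50 and 80 onward. Per-client round seeds derive from
(master seed, client, round) via SHA-256, so trajectories are pure functions
of configs and data.

* **FedAvg** aggregates the unweighted mean of client weight vectors. The
  source procedure prints the unweighted mean while describing it as
  "weighted"; the printed form is the default and an n_k-weighted variant
  sits behind `weighted_avg`.
* **FedProx** adds μ·(w − w_global) (μ = 0.01) to every local gradient; μ = 0
  reduces exactly to FedAvg.
* **FedOpt** treats Δ_t = w_t − mean(w_k) as a pseudo-gradient and applies an
  Adam-style server update (β₁ = 0.9, β₂ = 0.99, η_s = 0.01). The printed
  recurrences carry no bias-correction terms, so none are applied by default
  (a flag restores them). The sign convention (Δ as w_t minus the client
  mean, then a subtractive server step) moves the server toward the clients.
* Local optimizer: the DP procedure specifies a plain SGD step, which is the
  default; local Adam is available when DP is off, since the full-scale
  configuration nominally used Adam — which of the two the DP runs used is
  ambiguous in the source, so both paths exist and are tested.

## Differential privacy

Per batch: per-sample gradients are clipped to l2 norm C = 1.5 (norm floored
at 10⁻⁷ so the zero vector passes through), averaged, and Gaussian noise with
per-coordinate std η·C (η = 2.0) is added **to the batch average** — exactly
as the emulated procedure prints it. This is stronger noise than the common
DP-SGD convention (σ·C on the clipped sum, i.e. η·C/B on the average); the
alternative is available via `convention="sum_scaled"` for sensitivity
analysis but is not the default. No subsampling amplification is applied.
With FedProx, the data-independent proximal pull is added after the
clipped/noised gradient, outside the sensitivity bound.

Accounting is closed form: ε_step = √(2 ln(1.25/δ))/η with δ = 10⁻⁵
substituted directly into the per-step formula (this conflates per-step and
total δ, but it is the arithmetic being reproduced; the ledger keeps exact
values alongside). Composition over T = R·E·⌊n/B⌋ steps is reported both as
T·ε_step (basic) and √T·ε_step (the advanced-composition growth rate). The
printed-value protocol rounds ε_step to two decimals before linear
composition — that is how 12,500 × 2.42 ≈ 30,250 arises — and the ledger
reports both the exact and the printed-protocol values. η = 0 yields an
explicit infinite budget rather than an exception. The nominal 12,500-step
count uses 25 batches/epoch; per-manifest batch counts are also computable,
and the round log reports the budget of the busiest client.

## Evaluation

All metrics derive from the confusion grid: accuracy = trace/total, macro
precision/recall/F1 as unweighted class means with the conservative 0/0 → 0
convention (an absent or never-predicted class still counts in the mean).
Binary tasks report the same macro quantities so all result tables share one
schema. Per-class values and the full grid are always retained, and a
probability hook is kept so threshold-free metrics can be added.

## Orchestration and desk-scale profile

`run_experiment` executes generate → split → task view → partition →
federate → evaluate per (task, algorithm, seed) cell, caching each completed
cell as JSON keyed by its configuration (reruns are free; failures are
logged and skipped). The DP ablation grid runs FedAvg only, matching the
scope of the emulated DP experiments. All child seeds derive from the master
seed by component-tagged hashing.

The default desk profile — chosen once as a realistic small-scale analogue
and then frozen — is: N = 1,200 images at 64×64, K = 8 non-IID clients,
logistic model on 8×8 pooled features, R = 30 rounds, E = 2 local epochs,
B = 16, client learning rate 0.05. Under these conditions the full 3-task ×
3-algorithm matrix runs in under a minute and the qualitative recoveries
hold: best-federated accuracy tracks centralized within ~1 pp seed-averaged
on screening, accuracy decreases monotonically in the noise multiplier over
{0.5, 1, 2, 3}, and screening beats diagnosis by well over 10 pp for the
reference classifier.

## Known limitations

* Synthetic phantoms support relative/ordering claims only; no absolute
  accuracy here predicts performance on real ultrasound data.
* The desk-scale models are linear/shallow; architecture-specific FL effects
  (skip connections, attention) are represented only as cost-table metadata.
* Accounting is basic/advanced-composition arithmetic, not a Rényi-DP or
  moments accountant; the reported ε values are loose upper bounds by
  construction.
* Client sampling (<100% participation), stragglers, and real networking are
  out of scope; participation is always full.
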