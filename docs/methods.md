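# Methods

`vfaug` studies whether synthetic laryngoscopy-style images generated by
denoising diffusion probabilistic models (DDPMs) can mitigate severe class
imbalance in vocal-fold structural pathology (VFSP) classification. Real
clinical frames cannot be redistributed, so the package ships a procedural
phantom generator that reproduces the *statistical and structural* properties
of such a dataset, and every downstream stage — diffusion training, sampling,
curation, augmentation scenarios, evaluation — runs against it with known
ground truth.

## Diffusion model

The forward process corrupts an image `x0` (rescaled to [-1, 1]) at timestep
`t` of `T` as

    x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps,   eps ~ N(0, I),

with the cosine schedule

    abar_t = f(t) / f(0),   f(t) = cos^2( ((t/T + s) / (1 + s)) * pi/2 ).

`s` is a small offset preventing an abrupt first step; the package uses the
established convention `s = 0.008` (the source description calls it only "a
small constant"). Per-step quantities are derived from consecutive ratios:
`alpha_t = abar_t / abar_{t-1}`, `beta_t = 1 - alpha_t` clipped at 0.999 so
the last steps stay non-singular, and `abar` is then recomputed as the
cumulative product of the clipped `alpha`, which keeps the product identity
exact to 1e-9.

A denoiser `eps_theta(x_t, t)` is trained to predict the added noise by
minimizing `E ||eps - eps_theta(x_t, t)||^2` with uniform timestep sampling
and Adam at learning rate 1e-4. Ancestral sampling uses the standard
noise-prediction parameterization of the reverse mean,

    mu_theta = ( x_t - beta_t / sqrt(1 - abar_t) * eps_theta ) / sqrt(alpha_t),

with `sigma_t = sqrt(beta_t)` ("simple" variance) and `sigma = 0` at the
final step. These two choices (mean parameterization, sigma) are left
abstract in the source description; the noise-prediction form is the unique
one consistent with the training objective, and the simple variance is the
standard baseline.

Two denoisers implement the `predict_noise` contract:

* **U-Net** (images): conv-in, a residual block, stride-2 downsampling, a
  bottleneck residual block, nearest-neighbour upsampling with a
  skip-concatenation, a residual block, conv-out. Residual blocks are
  wide-ResNet style (GroupNorm, SiLU, 3x3 conv) with a per-block projection
  of the sinusoidal timestep embedding added as a channel bias. Attention
  blocks are omitted at desk scale (config switch reserved).
* **Residual MLP** (vectors): same timestep conditioning and residual
  pattern, used for distribution-level experiments where convolution is
  meaningless.

The whole stack — dense/conv layers (im2col + BLAS), GroupNorm, SiLU,
up/down-sampling, Adam — is implemented directly on NumPy with manual
backpropagation and is finite-difference-tested layer by layer and end to
end. All randomness flows through seeded `numpy.random.Generator` streams,
so training and sampling are bit-reproducible.

### Profiles

The published hyperparameter listings conflict (one lists epochs 1024 /
steps 10,000 / input 256 / batch 32; another 3072 epochs / 10,000 timesteps /
batch 16 / input 128), and whether "steps" means diffusion timesteps or
optimizer updates is ambiguous. The package exposes both a `paper` profile
(epochs 1024, `steps` interpreted as an optional cap on optimizer updates,
input 256, T = 10,000) and a `desk` profile (input 32, T = 200, channel
widths 16/32) without privileging either; every test runs the desk profile.
One unconditional model is trained per class; a class-conditional single
model is out of scope.

## Phantom generator

Each phantom frame is composed in a canonical coordinate frame and evaluated
through an inverse rotation, so geometry and lesion masks are exact: a
textured mucosa field, two elongated pale fold bands meeting anteriorly
around a dark glottal gap, a radial vignette, and one lesion archetype per
class following the standard clinical descriptions — two mirror-symmetric
mid-fold nodules; one rounded unilateral cyst; a reddish polyp protruding
medially from the fold edge; bilateral Reinke's widening; a dark sulcus
groove notching the medial fold edge; a posterior unilateral granuloma; a
whitish keratotic patch. `without_pathology` renders no lesion and an empty
mask.

Nuisance variation emulates handheld stroboscopy: rotation uniform in
±15°, global illumination gain ±20%, Gaussian sensor noise sigma 4 intensity
units, and mild optical blur (0.5 px). No quantitative appearance statistics
are published for the source data, so colors and lesion dimensions are
conventions; lesion sizes are chosen to remain legible at the 32 px desk
resolution (a few pixels across), since visually distinct archetypes are the
generator's purpose. Determinism: per-image RNG streams are derived by
hashing (label, seed), so datasets are byte-identical across platforms for
identical arguments.

`degrade` produces the failure modes the curation stage must catch: `blur`
(Gaussian, width = severity), `remove_folds` (folds, gap and lesion replaced
by mucosa — "no folds visible"), `triplicate_fold` (a third pale band
inserted lateral to the fold opposite any unilateral lesion — "three folds
appeared").

### What the phantoms do and do not show

Phantoms share the *structure* of laryngoscopic frames, not their
photometric richness: no specularities, mucus, vasculature, endoscope
distortion, or anatomical variability. Results on phantoms therefore
validate the pipeline's mechanics (count bookkeeping, leakage-free splits,
detectability of structural failures, the direction of augmentation
effects), not clinical performance on real imagery.

## Curation

The expert review of generative output is replaced by two measurable
criteria mirroring its stated grounds for rejection:

* **Sharpness** — variance of the Laplacian of luminance; the default
  threshold is the 5th percentile (lower method) of scores on the original
  dataset, so only images blurrier than essentially all originals fail.
* **Structure** — the central 60% crop of luminance is lightly smoothed
  (sigma scaled with image size), thresholded at 1.30x its median, and
  connected components that are large (>= 4% of the crop) and elongated
  (eccentricity >= 0.8) are counted; a plausible frame has exactly two such
  bands. A relative-median threshold replaces a fixed percentile share
  because a percentile always selects a fixed fraction of pixels and hence
  cannot report *zero* bands on fold-free images; the relative threshold is
  gain-invariant and empty on structureless input. Detector constants were
  tuned on phantoms (all 8 classes x 40 seeds x sizes 32/48/64 give exactly
  two bands; fold removal gives zero; triplication gives >= 3 at 64 px).

A manual override manifest (id -> keep) takes precedence over both criteria,
replicating true expert review. Reports partition the input exactly and are
serialized to JSON; rejected images are moved, never deleted.

## Augmentation scenarios and classifier

Tasks: binary (without vs with pathology; positive class = "with", matching
the high-sensitivity / low-specificity pattern of screening results) and
multi-class (the seven pathologies; the no-pathology class is excluded).

Scenarios: `synthetic_only` (train on all synthetic, test on all originals),
`mix10`/`mix50` (train adds 10% / 50% of originals, selected per class by
largest-remainder rounding — with 4 granuloma originals, mix10 contributes 0
and warns), and `original_only_baseline` (stratified 80/20 train/validation
on originals only). Splits are disjoint by id, test sets contain only
original images, and both properties are asserted at construction.
Largest-remainder rounding is also used for the stratified split; a class
with a single image goes to the training part with a warning.

The classifier follows the published training recipe exactly — batch 16,
Adam at 1e-4, integer-label cross entropy, 20 epochs, stratified 80/20 —
with a desk backbone: four conv blocks (3x3 conv, GroupNorm, SiLU, 2x2
average pool) with widths 16/32/64/64, global average pooling and a linear
head. Descriptors for the 16-layer and 50-layer reference architectures are
recorded but not instantiated. The "pre-trained" condition is modeled as
warm-starting from a user-supplied checkpoint; no external weights are ever
downloaded. The experiment grid repeats every (scenario, task) cell with
derived seeds (default 10; the desk benchmark uses 3) and reports sample
mean ± (n-1) SD per metric.

### The desk benchmark

The default benchmark keeps the study's bookkeeping where it matters most —
the full original per-class counts (404 images, 157:4 imbalance) — at 32 px,
and scales the synthetic corpus to 0.4 of the study's synthetic counts
(~1670 images), preserving a multiple-per-original augmentation volume
within CPU budgets. The synthetic stand-in is rendered by the phantom
generator with disjoint seeds and a "generative smoothing" style (blur 1.0
px, sensor noise 3): diffusion samples are smoother than camera frames, and
this mild domain gap is precisely what makes mixing original images into
training informative, as in the source experiments. Training eight DDPMs to
produce thousands of curated samples is far outside desk budgets; DDPM
training and sampling are instead exercised end to end at small scale in the
pipeline and by the distribution-recovery experiment below.

## Evaluation

Confusion matrices (rows actual, columns predicted) reduce one-vs-rest to
precision, sensitivity, specificity and F1; accuracy is trace/total. Binary
reports evaluate the positive class directly; multi-class reports average
one-vs-rest values (macro by default, weighted optional — the source's
multi-class specificity ≈ 0.96 is consistent with one-vs-rest averaging).
Zero-denominator metrics are 0 and flagged.

FID between feature sets is `||mu_r - mu_s||^2 + Tr(Sr + Ss - 2 (Sr Ss)^1/2)`
with the symmetrized square root `(Sr^1/2 Ss Sr^1/2)^1/2` computed by
eigendecomposition (negative eigenvalues clipped), covariances regularized
by 1e-6 I, and a zero floor. The desk feature extractor is a deterministic
PCA over flattened pixels fitted on the reference set (16 components by
default); the canonical pretrained inception network would require an
external weight download. An autoencoder extractor was considered and
rejected for the desk default because PCA is deterministic, fast and
stateless. Absolute FID values are extractor-specific and not comparable to
values computed with inception features; only orderings and differences
under a fixed extractor are meaningful, which the per-class FID table in the
pipeline reports.

## Benchmark experiments

* **Distribution recovery** — a residual-MLP diffusion model (hidden 96,
  3 blocks, lr 1e-3, 3000 updates, batch 128, T = 200) trained on a
  2-component 2-D Gaussian mixture (means (±0.7, ±0.7), SD 0.07, n = 2048)
  must place both sample-cluster means within 0.1 of the truth and put at
  least 95% of 1000 samples within 3 SD of a component. Measured errors are
  ~0.01-0.03 across seeds.
* **Directional headline** — on the desk benchmark, means over 3 repeats:
  the original-only multi-class baseline stays below 0.5 accuracy (it has
  ~198 training images with a 3-image minority class and a fixed 20-epoch
  budget), `mix50` exceeds 0.5, and `mix50` is at least as accurate as
  `synthetic_only` — the qualitative ordering of the source's result tables
  and its baseline-fails / augmented-converges contrast.

## Numerical and design choices

* beta clipped at 0.999; sigma = 0 at the final denoising step; `abar`
  recomputed from clipped alphas (product identity to 1e-9).
* Conv backprop via explicit col2im accumulation; GroupNorm backward uses
  the standard normalized-gradient form; all layers finite-difference
  checked.
* Seeds: one global seed; stage/repeat seeds derived by SHA-256 hashing of
  (seed, tags), truncated below 2^31.
* Aggregation uses sample (n-1) SD; a single report has SD 0 with n = 1
  recorded.
* Zero-denominator convention: affected metric is 0 and flagged in the
  report.
* The baseline's 80/20 validation metrics are reported as that scenario's
  test metrics (whether the source's baseline numbers are validation or test
  is unstated; the split is recorded either way).

## Known limitations

* Phantom realism is structural, not photometric; absolute metric values on
  phantoms say nothing about clinical data.
* The desk U-Net is far smaller than production diffusion backbones; at
  desk budgets its samples are useful for pipeline validation, not fidelity.
* FID values use a PCA extractor and are not comparable to
  inception-feature FIDs.
* The curation detector is tuned to the phantom appearance family; real
  laryngoscopy would need re-tuned constants or the manual-override path.
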