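# Methods

## The token-reconstruction objective

The package pretrains a vision transformer for fundus imaging by feature
distillation from itself: a frozen copy of the initial network (the teacher)
encodes clean images, and the trainable student must reproduce the teacher's
output tokens from corrupted inputs. Two corruptions are applied jointly to
every image except the last of each batch (kept clean so the student stays
robust to the absence of corruption):

- **Token corruption.** Per image, a ratio r ~ Uniform(0, 1/3) is drawn and
  round(r·N) of the N patch embeddings, chosen uniformly without replacement,
  are replaced by a single trainable corruption token. The replacement happens
  after the patch projection and *before* the positional embedding is added,
  so position is retained while content is erased. Class and register tokens
  are never corrupted. The expected masked fraction is E[U(0,1/3)] = 1/6.
- **Pixel noise.** i.i.d. Gaussian noise with σ = 0.2 is added element-wise in
  normalised intensity space (post-normalisation, where σ = 0.2 is
  scale-meaningful; on the 0.5/0.5 scheme this is 0.1 in raw intensity).

The loss is the plain mean squared error over all tokens (class, register,
and patch — registers carry global context and reconstructing them is part of
the objective) and all embedding dimensions, averaged over the batch. Whether
the corruption ratio is drawn per image or per batch, and whether noise is
added pre- or post-normalisation, were genuinely open choices; per-image
draws maximise within-batch diversity and are what this package commits to.

### Architecture

The student is a standard pre-norm ViT (patch projection, learned positional
embeddings, multi-head attention blocks with 4× GELU MLPs, final LayerNorm)
with one class token and four register tokens. The full-size configuration is
the small-ViT class: embedding dimension 384, patch size 14 at 392×392 input,
giving (392/14)² + 1 + 4 = 789 tokens. Patch size 14 (not 16) is required
because 392 is not divisible by 16. All sizes are configurable; the test and
demo configuration is embed 32, depth 2, heads 2, patch 8 at 64×64
(69 tokens).

Two training-only extras are attached. A trainable **corruption token**
(removed by checkpoint stripping), and a **residual projector**:
LayerNorm → Linear(d,d) → GELU → Linear(d,d), whose output is multiplied by a
learnable element-wise scale and added to the final tokens. The scale is
initialised to zero — the one initialisation that makes the projected output
*exactly* equal the backbone output, so that with a parameter-identical
frozen teacher and a clean batch the loss at step 0 is exactly zero. This
identity is load-bearing: it anchors the numerical contract of the training
loop (and a regression away from it indicates a divergence between the
teacher and student forward paths).

The designated image embedding is the class-token output; mean pooling over
patch tokens is available via `BackboneConfig.embedding="mean_patch"`.

### Optimisation

AdamW with β₁ = 0.9, β₂ = 0.99, weight decay 5e-4 applied to everything
except bias parameters; learning rate schedule: linear warmup from 5e-9 to
5e-5 over 10 epochs, cosine decay back to 5e-9, and a final 20-epoch cooldown
held at the minimum (defaults for the 120-epoch, batch-128 full-scale
configuration). The global gradient norm is clipped to 0.1 before every step.
The teacher is frozen at initialisation with no momentum/EMA update — its
parameter hash is identical before and after training, which the tests check.
Reference numerics are float32 throughout; the implementation runs on NumPy
with an in-package reverse-mode autodiff engine (exact erf-based GELU,
softmax with the standard Jacobian-vector product, LayerNorm composed from
primitive ops).

## Preprocessing

Fundus photographs are circular discs on black background, often with
horizontal black side space or slight top/bottom truncation. The square
pipeline: grayscale = channel mean, threshold at 0.05 of the maximum
intensity, largest 4-connected component, crop to its bounding box, pad the
shorter dimension symmetrically with black (odd pixel to the bottom/right),
resize (bilinear by default) to the target side (default 1024). This
preserves the disc aspect ratio within 1% through the pipeline and is
idempotent up to interpolation noise. The detection rule is the package's own
choice — the simplest robust one for dark-background photographs; threshold
and interpolation are configurable. Downstream evaluation deliberately uses
plain resize + normalisation only (the square pipeline is exposed but off by
default for evaluation), keeping comparisons between models independent of
preprocessing quality.

Normalisation schemes: mean = std = 0.5 on all channels for models trained
here; the ImageNet constants (0.485/0.456/0.406, 0.229/0.224/0.225) for
comparators that use them.

Patient-level splitting shuffles distinct patient ids and assigns
round(0.8·n) of them to training, guaranteeing no patient contributes images
to both sides.

## Augmentation

Colour jitter (brightness/contrast/saturation factors within ±0.1) plus
rotation (±10°) with probability 0.25; black side padding with independently
sampled left/right widths in [33, 150] px with probability 0.10 (simulating
poorly cropped images, decorrelated from any particular source); global
rescale by U(0.80, 1.20); then one of three uniformly chosen routes to the
square target resolution (default 392): plain resize, random resized crop
with area scale U(0.70, 1.00), or centre crop after a 1.3× upscale. The
jitter and rotation magnitudes are not pinned down by any external reference
and are configurable; the defaults are deliberately slight. Plan sampling is
separated from plan application so branch statistics can be audited cheaply
(the tests check the 0.25/0.10 frequencies and mode uniformity by χ²).

## Evaluation protocol

**Linear probing.** Logistic regression with its default L2 penalty,
max_iter = 20,000, on embeddings standardised to zero mean/unit variance with
the scaler fit on the training set only (a train+test scaler is a leakage bug
the tests guard against). Binary targets get one binary fit (d + 1
parameters: 385 at d = 384); graded targets (e.g. 5-way retinopathy grade)
get a single multinomial fit, with per-grade AUCs derived one-vs-rest from
the predicted probabilities — the derivation rule is this package's choice.

**Projections.** PCA and UMAP to 2-D, fit on the training set only, applied
to unseen rows. UMAP uses cosine distance by default (preferable for
high-dimensional network features), fixed random_state, single-threaded for
determinism; sensitivity variants run UMAP (cosine or Euclidean) on the first
100 principal components. Separation quality is quantified by a single
binary logistic probe (no rescaling — 2-D magnitudes are meaningful) and KNN
with k = 5 on the projected coordinates; KNN can exploit multi-cluster
structure a linear probe cannot, which a constructed two-cluster fixture
demonstrates.

**Transportability.** Scaler, projection, and classifier fitted on dataset A
are applied frozen to dataset B; nothing is refit.

**Class filter.** For many-class datasets, a class is reported as a target
only if at least one compared model scores strictly below 0.95 AUC on it
(exactly 0.95 drops, per the strict inequality); dropped classes remain in
the evaluation sets as negatives so the task is not made easier.

**Statistics.** The test set is bootstrapped 100 times at full size with the
same index sets for every model; the median AUC is reported. Best vs second
best (by median) are compared with a two-sided Wilcoxon signed-rank test
across the 100 paired AUCs; a win is p < 0.05, otherwise a tie. Zero
differences are discarded (classic signed-rank), with p = 1 when all are
zero. Resamples lacking one class are redrawn (up to 1000 attempts).
Wins/ties are tallied per target; p-values are never aggregated across
targets, and no confidence intervals are produced (bootstrap AUC columns of
different models share resampling noise, so interval overlap is
uninformative).

## Resource accounting

Compute is measured in A100 days: (gpu_hours / 24) × n_gpus ×
relative_throughput, reported to 2 decimals. Cost assumes an 8-GPU machine at
$30/hour: (A100 days / 8) × 24 × 30 — e.g. 112 days → $10,080; 163 days →
$14,670; 0.27 days → $24.30. A hook accepts a user-supplied kg-CO₂-per-kWh
factor, but no emission factors are shipped. Embedding storage is
n × d × 4 bytes for float32; the fold ratio of a 1024-d store over a 384-d
store is 2.67. Checkpoint stripping removes optimizer moments and
training-only heads, keeping only the inference backbone, and provably leaves
embeddings bit-identical.

## The synthetic study conditions

The generator renders a circular disc (default radius 0.42 of the frame) with
radial shading and texture noise, dark random-walk vessel polylines (purely
cosmetic, not label-bearing), a bright optic disc, and grade-dependent bright
lesion specks of 2–4 px radius with counts (0, 3, 8, 16, 30) for grades 0–4 —
class signal deliberately carried by small structures, since tiny lesions are
what distinguishes diseased from healthy retinas in real photographs. Side
bars (probability 0.3) and top/bottom truncation (probability 0.2) emulate
the acquisition artifacts the preprocessing must handle. Ground-truth
geometry is recorded exactly (the disc's rendered pixel bounding box equals
the recorded centre/radius box, which the tests scan for). All output is
deterministic under the seed.

What the synthetic data does **not** emulate: photographic colour profiles
and camera clusters, image-quality degradation, anatomical variation beyond
the disc/vessel/lesion sketch, and label noise. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and statistics, not
clinical performance.

**Desk-scale pretraining demo** (`fundusfm.workflows`): 256 images from 128
synthetic patients at 64×64, tiny backbone, batch 16, 200 steps, peak
learning rate 3e-3 (the 5e-5 of the 120-epoch full-scale configuration is too
small to produce measurable progress in 200 steps; warmup/cosine/cooldown
shape and the 0.1 clip are retained). Under these conditions the
corrupted-batch loss falls well below half its initial value.

**Known limitation.** At desk scale the frozen teacher is itself randomly
initialised, so the student's fixed point is a random network's
representation; the downstream advantage of pretrained over random-init
embeddings on the lesion-grade probe is real under the pinned demo seed but
small and seed-dependent. The full-scale method distils from a strong
pretrained teacher, which a from-scratch desk run cannot replicate — the demo
shows the mechanics of the objective, not the magnitude of its benefit.

## Numerical choices and degenerate inputs

- Float32 reference numerics; batched and single-image forward passes agree
  to < 1e-5 (BLAS reduction-order differences only).
- Odd crop/pad pixels go to the bottom/right; detection on an all-black image
  raises an "empty fundus" error; degenerate crop boxes are rejected.
- Corruption with ratio_upper = 0 yields empty masks; σ = 0 noise is the
  identity; masked-row replacement is exact (not approximate arithmetic).
- Learning-rate queries outside [0, epochs) raise; warmup + cooldown must be
  shorter than the run.
- Probes are deterministic (penalised logistic regression has a unique
  optimum); AUCs below 0.5 are reported as computed and flagged for display
  as "worse than random" by downstream plotting, never clipped.
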