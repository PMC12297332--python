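# fundusfm

Self-supervised pretraining and evaluation tooling for retinal colour fundus
imaging, built around a **token-reconstruction** objective: a frozen teacher
network sees clean images, a trainable student sees corrupted versions of the
same images, and the student is penalised for the mean squared error between
its output tokens and the teacher's. Because reconstruction happens in the
network's abstract token space rather than pixel space, the student must learn
the structure and co-dependencies of fundus images — where anatomy occurs,
what the presence of small lesions in one patch implies about the rest — which
is exactly the information a foundation-model embedding should carry.

The package is aimed at researchers prototyping compute-efficient foundation
models for fundus photography (and, more broadly, any imaging domain with low
high-level diversity where small structures carry the diagnosis). Everything
is exercisable end to end on synthetic fundus-like images, so no clinical data
or GPU is required to run, test, or extend the code.

## What's inside

| Module | Role |
| --- | --- |
| `fundusfm.synthetic` | deterministic generator of fundus-like images (disc, vessels, optic disc, grade-dependent lesion specks, acquisition artifacts), patient-structured label tables, Gaussian-blob embedding fixtures |
| `fundusfm.prep` | fundus-area detection, aspect-preserving square crop/pad, resize, per-model normalisation (mean/std 0.5, or the ImageNet constants), patient-level 80/20 splits |
| `fundusfm.augment` | the pretraining augmentation recipe (25% jitter+rotation, 10% side padding of 33–150 px, 80–120% rescale, one of three resize modes to 392×392) |
| `fundusfm.model` | ViT student with class token, four register tokens, trainable corruption token, residual projector head (NumPy, in-package autodiff) |
| `fundusfm.tokrecon` | corruption sampling (ratio ~ U(0, 1/3)), pixel noise N(0, 0.2), MSE token loss, AdamW with warmup/cosine/cooldown schedule, the training loop |
| `fundusfm.embed_store` | embedding extraction and persistence, checkpoint stripping, storage accounting |
| `fundusfm.probe_eval` | linear probing, PCA/UMAP 2-D projections with probes, external transportability, non-trivial-class filter |
| `fundusfm.stats_compare` | paired 100-bootstrap median AUC, two-sided Wilcoxon signed-rank best-vs-second, win/tie tallies |
| `fundusfm.resources` | A100-day and training-cost arithmetic |

A `fundusfm` command-line tool wraps the library
(`synth`, `prep`, `pretrain`, `embed`, `strip-ckpt`, `probe`, `project`,
`compare`, `resources`).

## The objective

Given an image $x$, the frozen teacher $f$ produces output tokens $f(x)$
(class token, 4 register tokens, and one token per 14×14 patch; embedding
dimension 384 in the full configuration, so a binary linear probe has
385 parameters). The student $g$ receives a corrupted $\tilde{x}$: per image a
corruption ratio $r \sim U(0, \tfrac13)$ selects $\mathrm{round}(rN)$ patches
whose embeddings are replaced by a trainable corruption token, and pixel-wise
Gaussian noise $\mathcal{N}(0, 0.2)$ is added in normalised intensity space.
The last image of each batch stays clean. The loss is

$$\mathcal{L} = \big\lVert\, g(\tilde{x}) + s \odot \mathrm{MLP}(g(\tilde{x})) - f(x) \,\big\rVert_2^2 \big/ \, nd$$

where the residual projector (LayerNorm–Linear–GELU–Linear, scaled by a
learnable element-wise vector $s$ initialised to zero) lets the student adapt
without perturbing its representation at the start: with $s = 0$ and a clean
batch the loss is exactly zero at initialisation. Training uses AdamW
(β₁ = 0.9, β₂ = 0.99, weight decay 5e-4, none on biases), a cosine schedule
warming up linearly from 5e-9 to 5e-5 over 10 epochs with a 20-epoch
final cooldown at the minimum, and global gradient-norm clipping at 0.1.

## Worked example

A desk-scale version of the whole pipeline — 256 synthetic fundus images from
128 "patients", a tiny backbone (embed 32, depth 2, patch 8 at 64×64), 200
training steps — runs in under a minute on a laptop CPU:

```python
from fundusfm.workflows import desk_scale_pretraining

result = desk_scale_pretraining(seed=0, n_steps=200)
print(f"loss {result['initial_loss']:.3f} -> {result['final_running_loss']:.3f}")
print(f"grade probe AUC: trained {result['trained_grade_auc']:.3f}, "
      f"random init {result['random_grade_auc']:.3f}")
```

```
loss 0.321 -> 0.034
grade probe AUC: trained 0.989, random init 0.970
```

The first line shows the student learning to reconstruct the frozen teacher's
tokens from corrupted inputs (the running loss falls to ~11% of its initial
value). The second line is the downstream check: a multinomial logistic probe
on the pretrained model's class-token embeddings ranks the synthetic lesion
grade better (macro one-vs-rest AUC on a patient-level held-out split) than
the same probe on embeddings from an untrained network of identical
architecture.

The resource arithmetic reproduces the familiar accounting for this family of
models, e.g.:

```python
from fundusfm.resources import ComputeSpec, a100_day_equivalent, training_cost
a100_day_equivalent(ComputeSpec(gpu_hours=8, n_gpus=1, relative_throughput=0.82))
# 0.27 A100 days
training_cost(112)   # $10,080 for two weeks on an 8-GPU machine
```

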