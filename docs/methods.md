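# Methods

## Problem setting

Few-shot image classification asks a model to recognise previously unseen
classes from a handful of labelled examples. Work is organised in
*episodes*: a task B = {S, Q} with `w` sampled classes, a support set S of
`k` labelled images per class (n = w·k) and a query set Q of `q` images per
class (m = w·q) to classify. The out-of-domain variant draws episodes from
an image distribution (modality, acquisition domain) different from anything
seen during pretraining — the regime where conventional few-shot methods
degrade most.

`protomae` implements a fully self-supervised answer: a vision-transformer
masked autoencoder is adapted *on each test episode itself*, using only the
episode's pixels, and the adapted encoder is then used as a metric backbone
for nearest-centroid (prototypical) classification. No label is consumed by
any training step at any stage.

## Model

**Backbone.** A ViT encoder–decoder in the masked-autoencoder arrangement:
images are split into non-overlapping `p×p` patches (row-major, channels
fastest), each flattened patch is linearly embedded, fixed 2-D sine/cosine
positional codes are added (learned positions are available by config), a
class token is prepended, and a pre-norm transformer stack encodes the
sequence. The design is asymmetric: the encoder sees only the *visible*
patches; a lighter decoder receives the projected visible tokens plus a
learned mask token at every hidden position (again with positional codes)
and predicts pixel content for all patches.

**Reconstruction loss.** For an image of width W and height H with pixels
s_ij (channel vectors) and predictions ŝ_ij,

    MSE = (1 / (W·H)) · Σ_i Σ_j ‖ŝ_ij − s_ij‖²₂,

averaged over the batch. The default scope sums over the full image with
visible patches composited from the input (so only hidden pixels contribute
error); a `masked_only` scope restricts both the sum and the normaliser to
masked-patch pixels. With compositing, the two differ only by the
normalising constant; both are exposed because loss magnitudes reported for
such models are not always comparable across conventions.

**Masking.** A mask hides exactly `round(ratio·L)` of the L patches
(round-half-away-from-zero, stated so masks are portable), drawn uniformly
without replacement; at least one patch must stay visible. The default ratio
is 0.75.

**Per-episode finetuning.** Given an episode, for each of N iterations the
loop visits every query image (support images may be included — they are
equally label-free — but are excluded by default), draws a randomly-resized
crop (area fraction uniform on [0.2, 1.0], log-uniform aspect in [3/4, 4/3],
resized back to model input size), samples a fresh mask, and takes one AdamW
step on the reconstruction loss. One optimizer step per image per iteration
(`per_image`) is the default; a `whole_set` mode takes a single step on the
stacked set per iteration and is faster but adapts far less (fewer optimizer
steps). Random-resized cropping is the only augmentation and is the main
guard against memorising the episode's few images. A diagnostic
`augment=False` mode disables cropping and freezes one mask per image, which
makes the loss a deterministic function of the parameters (used to verify
the no-update guarantees).

**Classification.** After finetuning, support and query images are embedded
by a full (unmasked) encoder pass; the embedding is the mean of the final
patch tokens (class-token pooling available by config; the mean is the more
robust choice for a retrofit metric). Class prototypes are arithmetic means
of support embeddings; queries take the label of the nearest prototype under
squared Euclidean distance (cosine available; under cosine, embeddings are
L2-normalised first). Exact distance ties break toward the lowest class
index. Embeddings are not L2-normalised under the Euclidean metric.

## Key parameters

| Parameter | Full-scale recipe | Desk scale | Notes |
|---|---|---|---|
| image size / patch | 224 / 16 px | 32 / 4 px | presets `vit-large-mae`, `vit-tiny-test` |
| encoder | 24 layers, dim 1024, 16 heads | 4 layers, dim 64, 4 heads | |
| decoder | 8 layers, dim 512, 16 heads | 2 layers, dim 32, 4 heads | decoder width/heads for the large preset follow the usual MAE pairing |
| MLP ratio | 4 | 2 | narrower MLP keeps the tiny model CPU-cheap |
| mask ratio | 0.75 | 0.75 | |
| finetuning iterations N | 1000 | 200 | one optimizer step per query image per iteration |
| finetuning lr | 1e-5 | 1e-3 | lr scales up as the model scales down |
| queries per class | 15 | 3 | desk episodes are kept small |
| episodes | 600–1000 | 50 | mean ± 1.96·sd/√n reported |
| optimizer | AdamW (0.9, 0.999), wd 0 | same | no schedule; none is warranted for short sessions |

The desk-scale study conditions are frozen in `protomae.harness`: two source
families (Gabor gratings, concentric rings) pooled for 300 steps of MAE
pretraining (batch 16, lr 1e-3), blob constellations held out as the
out-of-domain target, 5-way 5-shot episodes with 3 queries per class, model
reset to the pretrained weights before each episode (a carry-over mode
exists but is off: per-episode adaptation is the phenomenon of interest).

## Synthetic data

Four procedural families provide visually distinct "domains" at 32×32 RGB:
oriented Gabor-like gratings, blob constellations on a ring, concentric
rings, and warped checkerboards. Each class within a family is a mode of one
scalar generative parameter (orientation; constellation radius; radial
frequency; checker frequency), with class means spaced `class_separation`
parameter units apart, per-image parameter jitter of fixed width, a random
per-channel tint, and additive Gaussian pixel noise (sd 0.05 by default),
clipped to [0, 1]. Collections are exactly class-balanced and bitwise
reproducible from their seed.

The generator emulates only the *structure* of a cross-domain few-shot
benchmark — several separable classes inside each of several mutually
dissimilar image distributions — not the appearance of skin lesions, blood
cells or satellite tiles. Real images have far richer within-class variation
(pose, illumination, clutter) and far weaker raw-pixel separability, so a
passing desk suite shows the machinery and the direction of the effect, not
performance on any real modality.

## Numerical and engineering choices

- The networks are trained by a small tape-based reverse-mode autodiff
  engine on numpy arrays with fused transformer primitives (affine, layer
  norm, tanh-GELU, packed-qkv attention, token gather/scatter, weighted
  squared error). Every primitive, and the assembled model, is checked
  against central finite differences in float64.
- Layer norm, GELU and the Adam moment update are JIT-compiled with numba
  when available (pure-numpy fallbacks implement identical math): at desk
  batch sizes these elementwise kernels, not BLAS, dominate step time.
- All forward/backward work is float32; evaluation embeddings are computed
  with the tape disabled.
- Parameters initialise from N(0, 0.02) (Xavier-scaled for the patch
  embedding and heads), layer norms at (1, 0).
- Crop resampling is bilinear with half-pixel centers and edge replication;
  a full-size crop is returned exactly, so a (1, 1) scale range with unit
  aspect is the identity.
- Determinism: every stochastic component takes a `numpy` Generator or an
  integer seed; episode streams spawn independent child seeds; identical
  configs and seeds reproduce results bitwise on the same platform.
- Degenerate inputs are rejected explicitly (masks covering all patches,
  empty visible sets, episodes over-drawing a class, non-finite losses abort
  with the offending iteration named).

## Design choices where the design was open

- **Embedding pooling** (mean vs class token) and **pixel normalisation**
  (raw [0, 1] vs per-image channel standardisation) are config switches, with
  mean pooling over raw pixels the default.
- **Loss scope**: the area-normalised full-image form is the default, with
  compositing making it a rescaled masked-only loss; both scopes are
  first-class.
- **Table-style "query images per episode"** is read per class (the standard
  convention); an episode-wide total mode exists.
- **`include_support`** defaults to false — the finetuning loop enumerates
  query images only — but support images can be added, since the loop never
  reads labels either way.
- **Reset policy**: the model is reset to pretrained weights before each
  episode by default; carry-over across episodes is exposed for study.
- **Batch mode**: `per_image` is the default and is what the desk benchmark
  uses; the number of optimizer steps (N × n_q), not the number of images
  per step, is what drives adaptation at this scale.

## What the desk benchmark shows

With the frozen conditions above, pretraining reduces source reconstruction
loss several-fold; on held-out target episodes the finetuning loss trace
falls within episodes, and finetuned accuracy exceeds the un-finetuned
baseline on the same episodes (paired one-sided t-test at α = 0.05 over 50
episodes). The acceptance script (`scripts/acceptance.py`) recomputes these
quantities from scratch at any seed.

## Known limitations

- The tiny backbone's absolute accuracies are far from ceiling; the
  benchmark is designed to measure the *adaptation gain*, not peak accuracy.
- Source-domain pretraining at this scale mainly provides a stable
  initialisation; most class-relevant target structure is learned during
  the per-episode sessions. At full scale, a strongly pretrained encoder
  shifts more of the work to pretraining.
- Adaptation cost scales linearly with N × n_q single-image optimizer steps;
  CPU wall time is the practical bound on episode counts.
- The checkpoint adapter for externally pretrained ViT weights maps configs
  and shapes only; bit-exact import of third-party checkpoints is not
  guaranteed.
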