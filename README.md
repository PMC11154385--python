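# protomae

Self-supervised per-episode finetuning of a masked autoencoder for
out-of-domain few-shot image classification.

## The problem

Few-shot classifiers are asked to recognise new classes from a handful of
labelled examples, organised as episodes: `w` sampled classes, a support set
of `k` labelled images per class, and a query set to classify. When test
episodes come from a different image domain than the one the backbone was
pretrained on (a new imaging modality, a new sensor), metric- and
meta-learning approaches degrade sharply — and most remedies lean on
supervised finetuning with the support labels.

`protomae` implements the fully self-supervised alternative: adapt the
backbone **on each episode itself**, using only the episode's pixels.

1. **Pretrain** a ViT masked autoencoder (MAE) on source-domain images:
   75% of the patches are hidden, the encoder sees only the visible ones,
   and a light decoder reconstructs the image, minimising the
   area-normalised squared error
   `MSE = (1/(W·H)) Σᵢⱼ ‖ŝᵢⱼ − sᵢⱼ‖²`.
2. **On-line finetuning**: for each test episode, loop `N` iterations over
   the episode's query images — randomly-resized crop, fresh random mask,
   one optimizer step on the reconstruction loss. No label is read.
3. **Classify** as a prototypical network: embed support and query images
   with the adapted encoder, average support embeddings into per-class
   centroids, assign each query to the nearest centroid.

The library ships both the full-scale recipe (`vit-large-mae` preset:
224 px images, 16 px patches, 24/8 encoder/decoder layers, 1000 finetuning
iterations at lr 1e-5) and a desk-scale configuration (`vit-tiny-test`,
32 px images) that runs the complete pipeline on one CPU, paired with a
procedural multi-domain image generator so that pretraining and genuinely
out-of-domain episodic evaluation need no downloads. The models are trained
by the package's own compact numpy autodiff engine (`protomae.autodiff`),
gradient-checked against finite differences.

## Worked example

```python
from protomae import (
    MaskedAutoencoder, PRESETS, evaluate, paired_gain_test, pretrain_mae,
)
from protomae.harness import desk_benchmark, desk_eval_config

# two source families pooled for pretraining; blob constellations held out
pretrain_coll, target_coll = desk_benchmark(seed=0)

model = MaskedAutoencoder(PRESETS["vit-tiny-test"], seed=0)
model, trace = pretrain_mae(model, pretrain_coll, steps=300, lr=1e-3, seed=0)

# 50 paired 5-way 5-shot episodes: finetuned vs. frozen on the same episodes
results, agg = evaluate(model, target_coll, desk_eval_config(50, seed=0))
t, p = paired_gain_test(results)
print(f"finetuned {agg.mean_accuracy:.3f} ± {agg.ci95_halfwidth:.3f}")
print(f"baseline  {agg.mean_baseline:.3f}   gain {agg.gain:+.3f}  (p = {p:.2e})")
```

Output (seed 0):

```
finetuned 0.487 ± 0.058
baseline  0.329   gain +0.157  (p = 2.14e-05)
```

Reading: on episodes drawn from an image family the model never saw during
pretraining, nearest-centroid accuracy with the frozen encoder is 32.9%;
after 200 label-free finetuning iterations on each episode's own query
pixels it rises to 48.7%. The `± 0.058` is the 95% interval
(`1.96·sd/√50`), and the paired one-sided t-test rejects "no gain" at
p ≈ 2×10⁻⁵. Pretraining loss fell 0.795 → 0.191 over its 300 steps, and the
per-episode finetuning traces decrease within episodes — reconstruction
improvement and accuracy improvement move together.

The same pipeline is scriptable from the shell:

```bash
protomae synth --family concentric_rings --n-classes 8 --out data/rings
protomae pretrain --data data/rings --steps 300 --out rings.npz
protomae eval --checkpoint rings.npz --data data/blobs --episodes 50
protomae ablate --checkpoint rings.npz --data data/blobs --axis iterations --values 0,50,200
protomae demo --check        # end-to-end desk benchmark, nonzero exit on failure
```

Real image collections are read from the standard class-per-subdirectory
folder layout (`root/class_name/*.png|jpg`).

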