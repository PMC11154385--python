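"""End-to-end evaluation: pretraining, paired episodic evaluation, ablations.

The canonical experiment has three stages. (1) The autoencoder is pretrained
self-supervisedly on a pooled source-domain collection. (2) Episodes are
drawn from a held-out target domain; on each episode the model is
(optionally) reset to the pretrained weights and finetuned on-line with the
reconstruction objective, then the support images are embedded, class
centroids computed, and the query images classified by nearest centroid.
(3) When ``compare_baseline`` is set, the identical episode is also
classified with the un-finetuned model, giving a paired with/without
comparison whose mean difference is the self-supervised adaptation gain.

Mean accuracy is reported with the conventional normal-approximation 95%
interval, ``1.96 * sd / sqrt(n_episodes)``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .backbone import ConfigurationError, PRESETS, patchify
from .episodes import Episode, EpisodeSpec, LabelledImage, episode_stream
from .finetune import FinetuneConfig, LossTrace, online_finetune
from .mae import MaskedAutoencoder, sample_mask
from .optim import make_optimizer
from .protonet import classify, compute_centroids, episode_accuracy
from .synthetic_data import BenchmarkSizes, make_benchmark


@dataclasses.dataclass(frozen=True)
class EvalConfig:
    episode_spec: EpisodeSpec = dataclasses.field(default_factory=EpisodeSpec)
    n_episodes: int = 600
    finetune: FinetuneConfig = dataclasses.field(default_factory=FinetuneConfig)
    reset_per_episode: bool = True
    compare_baseline: bool = True
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self):
        if self.n_episodes < 1:
            raise ConfigurationError("n_episodes must be >= 1")


@dataclasses.dataclass
class EpisodeResult:
    accuracy: float
    baseline_accuracy: float | None
    loss_trace: LossTrace
    episode_seed: int

    @property
    def gain(self) -> float | None:
        if self.baseline_accuracy is None:
            return None
        return self.accuracy - self.baseline_accuracy


@dataclasses.dataclass
class AggregateResult:
    mean_accuracy: float
    ci95_halfwidth: float
    n_episodes: int
    mean_baseline: float | None = None
    baseline_ci95_halfwidth: float | None = None
    gain: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def aggregate(results: Sequence[EpisodeResult]) -> AggregateResult:
    accs = np.array([r.accuracy for r in results], dtype=np.float64)
    n = accs.size
    ci = float(1.96 * accs.std(ddof=0) / np.sqrt(n))
    out = AggregateResult(
        mean_accuracy=float(accs.mean()), ci95_halfwidth=ci, n_episodes=n
    )
    if all(r.baseline_accuracy is not None for r in results):
        base = np.array([r.baseline_accuracy for r in results], dtype=np.float64)
        out.mean_baseline = float(base.mean())
        out.baseline_ci95_halfwidth = float(1.96 * base.std(ddof=0) / np.sqrt(n))
        out.gain = out.mean_accuracy - out.mean_baseline
    return out


def paired_gain_test(results: Sequence[EpisodeResult]) -> tuple[float, float]:
    """One-sided paired t-test of 'mean gain > 0'; returns (t, p)."""
    gains = np.array([r.gain for r in results], dtype=np.float64)
    if np.allclose(gains, gains[0]):
        # degenerate: identical gains (e.g. N=0 everywhere); no evidence either way
        return 0.0, 1.0 if gains[0] <= 0 else 0.0
    t, p = stats.ttest_1samp(gains, 0.0, alternative="greater")
    return float(t), float(p)


def pretrain_mae(
    model: MaskedAutoencoder,
    collection: Sequence[LabelledImage],
    steps: int,
    batch_size: int = 16,
    mask_ratio: float = 0.75,
    lr: float = 1e-3,
    seed: int = 0,
    optimizer: str = "adamw",
    loss_scope: str = "full_image",
) -> tuple[MaskedAutoencoder, LossTrace]:
    """Standard masked-autoencoder pretraining on a pooled collection.

    Each step samples a batch with replacement, hides a fresh random 75% (by
    default) of patches and takes one optimizer step on the reconstruction
    error. Labels in the collection are never read.
    """
    if steps < 0:
        raise ConfigurationError("steps must be nonnegative")
    cfg = model.config
    images = np.stack([np.asarray(it.image, dtype=np.float32) for it in collection])
    rng = np.random.default_rng(seed)
    opt = make_optimizer(optimizer, model.params, lr=lr)
    trace = np.empty(steps, dtype=np.float64)
    for step_i in range(steps):
        idx = rng.choice(images.shape[0], size=min(batch_size, images.shape[0]), replace=True)
        mask = sample_mask(cfg.num_patches, mask_ratio, rng)
        patches = patchify(images[idx], cfg).patches
        loss = model.training_loss(patches, mask, loss_scope)
        trace[step_i] = float(loss.data)
        if not np.isfinite(trace[step_i]):
            raise RuntimeError(f"non-finite pretraining loss at step {step_i}")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return model, LossTrace(trace)


def _classify_episode(model: MaskedAutoencoder, episode: Episode, metric: str) -> float:
    s_img, s_lab = episode.support_arrays()
    q_img, q_lab = episode.query_arrays()
    protos = compute_centroids(model.encoder.embed_image(s_img), s_lab, metric)
    preds = classify(model.encoder.embed_image(q_img), protos)
    return episode_accuracy(preds, q_lab)


def evaluate(
    model: MaskedAutoencoder,
    target_collection: Sequence[LabelledImage],
    config: EvalConfig,
    log_path: str | Path | None = None,
    save_weights_dir: str | Path | None = None,
) -> tuple[list[EpisodeResult], AggregateResult]:
    """Paired episodic evaluation of on-line finetuning on a target collection.

    The baseline ("without finetuning") arm sees the exact same episode
    stream. ``model`` is left at the pretrained weights on return when
    ``reset_per_episode`` is set; in carry-over mode it keeps the weights of
    the final episode. With ``save_weights_dir`` the finetuned weights of
    every episode are checkpointed there (off by default: one file per
    episode adds up quickly).
    """
    base_state = model.state()
    baseline = model.copy() if config.compare_baseline else None
    if save_weights_dir is not None:
        save_weights_dir = Path(save_weights_dir)
        save_weights_dir.mkdir(parents=True, exist_ok=True)
    log_fh = open(log_path, "w") if log_path else None
    results: list[EpisodeResult] = []
    try:
        episodes = episode_stream(
            target_collection, config.episode_spec, config.n_episodes, config.seed
        )
        for idx, episode in enumerate(episodes):
            if config.reset_per_episode:
                model.load_state(base_state)
            ft_seed = int(
                np.random.SeedSequence([config.seed, 7919 + idx]).generate_state(1)[0]
                % 2**31
            )
            ft_cfg = dataclasses.replace(config.finetune, seed=ft_seed)
            _, trace = online_finetune(model, episode, ft_cfg)
            if save_weights_dir is not None:
                model.save(save_weights_dir / f"episode_{idx:04d}.npz")
            acc = _classify_episode(model, episode, config.metric)
            base_acc = (
                _classify_episode(baseline, episode, config.metric)
                if baseline is not None
                else None
            )
            result = EpisodeResult(
                accuracy=acc, baseline_accuracy=base_acc,
                loss_trace=trace, episode_seed=ft_seed,
            )
            results.append(result)
            if log_fh:
                log_fh.write(json.dumps({
                    "episode": idx, "accuracy": acc, "baseline_accuracy": base_acc,
                    "final_loss": float(trace.per_iteration_loss[-1]) if len(trace) else None,
                    "episode_seed": ft_seed,
                }) + "\n")
        if config.reset_per_episode:
            model.load_state(base_state)
    finally:
        if log_fh:
            log_fh.close()
    return results, aggregate(results)


def run_ablation(
    model: MaskedAutoencoder,
    target_collection: Sequence[LabelledImage],
    axis: str,
    values: Sequence,
    base_config: EvalConfig,
) -> list[dict]:
    """Paired grid over one ablation axis; shared episode seeds across arms.

    ``axis`` is ``"iterations"``, ``"learning_rate"`` or ``"backbone"``; for
    the backbone axis each value is a ready (pretrained) MaskedAutoencoder or
    a (name, model) pair. Returns one row per value with the aggregate
    numbers.
    """
    if axis not in ("iterations", "backbone", "learning_rate"):
        raise ConfigurationError("axis must be iterations, backbone or learning_rate")
    if len(values) < 2:
        raise ConfigurationError("an ablation needs at least two values")
    rows = []
    for value in values:
        arm_model = model
        label = value
        if axis == "iterations":
            cfg = dataclasses.replace(
                base_config,
                finetune=dataclasses.replace(base_config.finetune, iterations=int(value)),
            )
        elif axis == "learning_rate":
            cfg = dataclasses.replace(
                base_config,
                finetune=dataclasses.replace(base_config.finetune, learning_rate=float(value)),
            )
        else:
            label, arm_model = value if isinstance(value, tuple) else (str(value), value)
            cfg = base_config
        results, agg = evaluate(arm_model, target_collection, cfg)
        rows.append({
            "axis": axis, "value": label,
            "mean_accuracy": agg.mean_accuracy,
            "ci95_halfwidth": agg.ci95_halfwidth,
            "mean_baseline": agg.mean_baseline,
            "per_episode_accuracy": [r.accuracy for r in results],
            "per_episode_baseline": [r.baseline_accuracy for r in results],
        })
    return rows


def write_results(
    results: Sequence[EpisodeResult],
    agg: AggregateResult,
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> None:
    """Persist a run as a JSON summary and/or per-episode CSV table."""
    if json_path:
        Path(json_path).write_text(json.dumps(agg.to_dict(), indent=2))
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["episode", "accuracy", "baseline_accuracy", "gain"])
            for i, r in enumerate(results):
                writer.writerow([i, r.accuracy, r.baseline_accuracy, r.gain])


# --------------------------------------------------------------- desk scale

#: families used by the default desk benchmark: two source domains for
#: pretraining and one held-out, out-of-domain target for episodes
DESK_SOURCE_FAMILIES = ("gabor_textures", "concentric_rings")
DESK_TARGET_FAMILY = "blob_constellations"
DESK_PRETRAIN_STEPS = 300
DESK_PRETRAIN_LR = 1e-3
DESK_FINETUNE_ITERATIONS = 200
DESK_FINETUNE_LR = 1e-3


def desk_benchmark(seed: int = 0, sizes: BenchmarkSizes | None = None):
    """The default synthetic out-of-domain benchmark collections."""
    return make_benchmark(
        DESK_SOURCE_FAMILIES, DESK_TARGET_FAMILY, sizes=sizes, seed=seed
    )


def desk_finetune_config(seed: int = 0) -> FinetuneConfig:
    """Desk-scale finetuning recipe for the tiny backbone.

    The learning rate scales up as the model scales down (the full-scale
    recipe's 1e-5 lives in the ``vit-large-mae`` preset defaults). Iterations
    keep the per-image semantics: every iteration takes one optimizer step
    per query image.
    """
    return FinetuneConfig(
        iterations=DESK_FINETUNE_ITERATIONS,
        learning_rate=DESK_FINETUNE_LR,
        batch_mode="per_image",
        seed=seed,
    )


def desk_eval_config(n_episodes: int = 50, seed: int = 0) -> EvalConfig:
    return EvalConfig(
        episode_spec=EpisodeSpec(ways=5, shots=5, queries=3),
        n_episodes=n_episodes,
        finetune=desk_finetune_config(seed),
        reset_per_episode=True,
        compare_baseline=True,
        seed=seed,
    )


def desk_pretrained_model(
    pretrain_collection: Sequence[LabelledImage], seed: int = 0
) -> tuple[MaskedAutoencoder, LossTrace]:
    """Tiny-preset model pretrained on a desk-scale source collection."""
    model = MaskedAutoencoder(PRESETS["vit-tiny-test"], seed=seed)
    return pretrain_mae(
        model, pretrain_collection, steps=DESK_PRETRAIN_STEPS,
        batch_size=16, lr=DESK_PRETRAIN_LR, seed=seed,
    )


def run_desk_benchmark(seed: int = 0, n_episodes: int = 50) -> dict:
    """Full desk-scale experiment: generate, pretrain, paired-evaluate.

    Returns a summary dict with the with/without-finetuning accuracies, the
    gain, and the paired one-sided test of 'gain > 0'.
    """
    pretrain_coll, target_coll = desk_benchmark(seed=seed)
    model, pre_trace = desk_pretrained_model(pretrain_coll, seed=seed)
    results, agg = evaluate(model, target_coll, desk_eval_config(n_episodes, seed=seed))
    t, p = paired_gain_test(results)
    mean_trace = np.mean(
        [r.loss_trace.per_iteration_loss for r in results], axis=0
    )
    k = max(1, len(mean_trace) // 10)
    return {
        "n_episodes": n_episodes,
        "mean_accuracy": agg.mean_accuracy,
        "ci95_halfwidth": agg.ci95_halfwidth,
        "mean_baseline": agg.mean_baseline,
        "gain": agg.gain,
        "paired_t": t,
        "paired_p": p,
        "pretrain_first10pct_loss": float(np.mean(pre_trace.per_iteration_loss[:30])),
        "pretrain_last10pct_loss": float(np.mean(pre_trace.per_iteration_loss[-30:])),
        "finetune_first10pct_loss": float(mean_trace[:k].mean()),
        "finetune_last10pct_loss": float(mean_trace[-k:].mean()),
        "results": results,
    }
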