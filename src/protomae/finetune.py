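"""On-line self-supervised finetuning of the autoencoder on a single episode.

For each of ``iterations`` rounds the loop takes the episode's query images
(support images too, if requested — they are equally label-free), draws a
randomly-resized crop of each, hides a fresh random subset of patches, and
takes one optimizer step on the reconstruction error. No label is read at
any point: the adaptation signal is purely the pixel content of the episode,
which is what lets the procedure run on out-of-domain episodes where no
supervision exists.

Random resized cropping is the only augmentation; it is the main guard
against the loop memorising the handful of episode images.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path

import numpy as np

from .backbone import ConfigurationError, patchify
from .episodes import Episode
from .mae import MaskedAutoencoder, sample_mask
from .optim import make_optimizer


@dataclasses.dataclass(frozen=True)
class FinetuneConfig:
    """Per-episode finetuning recipe.

    Defaults mirror the full-scale recipe (1000 iterations at lr 1e-5 with
    75% masking); the desk-scale harness overrides ``iterations`` and
    ``learning_rate`` for its small backbone. ``batch_mode="per_image"``
    takes one optimizer step per image per iteration; ``"whole_set"`` takes a
    single step on the stacked set (one shared mask per step), which is
    faster. With ``augment=False`` cropping is disabled and each image keeps
    one fixed mask for the whole session — a diagnostic mode in which the
    loss is a deterministic function of the parameters.
    """

    iterations: int = 1000
    learning_rate: float = 1e-5
    mask_ratio: float = 0.75
    crop_scale_range: tuple[float, float] = (0.2, 1.0)
    crop_aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    include_support: bool = False
    optimizer: str = "adamw"
    optimizer_kwargs: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    batch_mode: str = "per_image"
    loss_scope: str = "full_image"
    composited: bool = True
    augment: bool = True

    def __post_init__(self):
        if self.iterations < 0 or self.learning_rate < 0:
            raise ConfigurationError("iterations and learning_rate must be nonnegative")
        if not 0.0 < self.mask_ratio < 1.0:
            raise ConfigurationError("mask_ratio must lie strictly in (0, 1)")
        low, high = self.crop_scale_range
        if not 0.0 < low <= high <= 1.0:
            raise ConfigurationError("crop_scale_range must satisfy 0 < low <= high <= 1")
        if self.batch_mode not in ("per_image", "whole_set"):
            raise ConfigurationError("batch_mode must be 'per_image' or 'whole_set'")


@dataclasses.dataclass
class LossTrace:
    """Reconstruction loss per finetuning iteration."""

    per_iteration_loss: np.ndarray

    def __post_init__(self):
        self.per_iteration_loss = np.asarray(self.per_iteration_loss, dtype=np.float64)

    def __len__(self) -> int:
        return self.per_iteration_loss.size

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loss"])
            for i, v in enumerate(self.per_iteration_loss):
                writer.writerow([i, v])

    def plot(self, path: str | Path, title: str = "finetuning loss") -> None:
        """Save a loss-vs-iteration curve as an image (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.plot(self.per_iteration_loss, lw=1)
        ax.set_xlabel("iteration")
        ax.set_ylabel("reconstruction loss")
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Vectorized bilinear resampling (half-pixel centers, edge replicate)."""
    h, w = img.shape[:2]
    ys = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    wy = (ys - y0).astype(img.dtype)[:, None, None]
    wx = (xs - x0).astype(img.dtype)[None, :, None]
    y0c = np.clip(y0, 0, h - 1)
    y1c = np.clip(y0 + 1, 0, h - 1)
    x0c = np.clip(x0, 0, w - 1)
    x1c = np.clip(x0 + 1, 0, w - 1)
    top = img[y0c][:, x0c] * (1 - wx) + img[y0c][:, x1c] * wx
    bot = img[y1c][:, x0c] * (1 - wx) + img[y1c][:, x1c] * wx
    return top * (1 - wy) + bot * wy


def sample_crop_geometry(
    h_img: int,
    w_img: int,
    scale_range: tuple[float, float],
    aspect_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Draw a crop rectangle: uniform area fraction, log-uniform aspect ratio.

    Returns (top, left, height, width); falls back to the full image after
    ten out-of-bounds proposals.
    """
    low, high = scale_range
    if not 0.0 < low <= high <= 1.0:
        raise ConfigurationError("scale_range must satisfy 0 < low <= high <= 1")
    area = h_img * w_img
    for _ in range(10):
        frac = rng.uniform(low, high)
        ar = math.exp(rng.uniform(math.log(aspect_range[0]), math.log(aspect_range[1])))
        w = int(round(math.sqrt(frac * area * ar)))
        h = int(round(math.sqrt(frac * area / ar)))
        if 0 < w <= w_img and 0 < h <= h_img:
            top = int(rng.integers(0, h_img - h + 1))
            left = int(rng.integers(0, w_img - w + 1))
            return top, left, h, w
    return 0, 0, h_img, w_img


def random_resized_crop(
    image: np.ndarray,
    scale_range: tuple[float, float],
    rng: np.random.Generator,
    aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0),
) -> np.ndarray:
    """Crop a random area fraction with aspect jitter, resize back to input size.

    The area fraction is uniform on ``scale_range``, the aspect ratio
    log-uniform on ``aspect_range``; if ten proposals in a row fall outside
    the image the whole image is used. A full-size crop is returned exactly
    (no resampling), so ``scale_range=(1, 1)`` with unit aspect is the
    identity transform.
    """
    h_img, w_img = image.shape[:2]
    top, left, h, w = sample_crop_geometry(
        h_img, w_img, scale_range, aspect_range, rng
    )
    crop = image[top : top + h, left : left + w]
    if crop.shape[:2] == (h_img, w_img):
        return np.array(crop, dtype=np.float32)
    out = _bilinear_resize(crop.astype(np.float32), h_img, w_img)
    return np.clip(out, 0.0, 1.0)


def online_finetune(
    model: MaskedAutoencoder, episode: Episode, config: FinetuneConfig
) -> tuple[MaskedAutoencoder, LossTrace]:
    """Finetune ``model`` in place on one episode; returns (model, loss trace).

    With ``iterations=0`` or ``learning_rate=0`` the returned parameters are
    bitwise identical to the input's.
    """
    cfg = model.config
    items = list(episode.query) + (list(episode.support) if config.include_support else [])
    images = [np.asarray(it.image, dtype=np.float32) for it in items]  # labels never read
    if not images:
        raise ConfigurationError("episode contains no images to finetune on")
    for img in images:
        if img.shape[0] != cfg.image_size or img.shape[1] != cfg.image_size:
            raise ConfigurationError(
                f"episode images {img.shape[:2]} do not match model "
                f"image_size {cfg.image_size}"
            )

    opt = make_optimizer(
        config.optimizer, model.params, lr=config.learning_rate, **config.optimizer_kwargs
    )
    rng = np.random.default_rng(config.seed)
    L = cfg.num_patches
    fixed_masks = None
    if not config.augment:
        fixed_masks = [sample_mask(L, config.mask_ratio, rng) for _ in images]

    def step(batch: np.ndarray, mask) -> float:
        patches = patchify(batch, cfg).patches
        loss = model.training_loss(patches, mask, config.loss_scope, config.composited)
        value = float(loss.data)
        opt.zero_grad()
        loss.backward()
        opt.step()
        return value

    trace = np.empty(config.iterations, dtype=np.float64)
    for it in range(config.iterations):
        if config.batch_mode == "per_image":
            losses = []
            for i, img in enumerate(images):
                view = (
                    random_resized_crop(
                        img, config.crop_scale_range, rng, config.crop_aspect_range
                    )
                    if config.augment
                    else img
                )
                mask = (
                    sample_mask(L, config.mask_ratio, rng)
                    if config.augment
                    else fixed_masks[i]
                )
                losses.append(step(view[None], mask))
            trace[it] = float(np.mean(losses))
        else:
            views = [
                random_resized_crop(
                    img, config.crop_scale_range, rng, config.crop_aspect_range
                )
                if config.augment
                else img
                for img in images
            ]
            mask = (
                sample_mask(L, config.mask_ratio, rng)
                if config.augment
                else fixed_masks[0]
            )
            trace[it] = step(np.stack(views), mask)
        if not np.isfinite(trace[it]):
            raise RuntimeError(
                f"non-finite reconstruction loss at finetuning iteration {it}"
            )
    return model, LossTrace(trace)
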