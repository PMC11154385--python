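"""Vision-transformer encoder primitives.

Images are stored height-first as (batch, H, W, C) arrays of floats in
[0, 1]. Patchification flattens non-overlapping square patches in row-major
order (top-left to bottom-right) with channels varying fastest, so masks and
reconstructions are portable across implementations. Positional information
is fixed 2-D sine/cosine by default (no training needed at desk scale); a
config switch enables learned positions instead.

The encoder consumes an arbitrary subset of patches — attention is
permutation-equivariant, and each visible patch carries the positional code
of its original grid location — which is what makes the masked-autoencoder
training loop in :mod:`protomae.mae` cheap: only the visible quarter of the
tokens flows through the deep encoder.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ConfigurationError(ValueError):
    """Raised when shapes/configs disagree (non-divisible sizes, bad masks...)."""


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for the encoder–decoder pair."""

    image_size: int
    patch_size: int
    channels: int = 3
    encoder_dim: int = 64
    encoder_layers: int = 4
    encoder_heads: int = 4
    decoder_dim: int = 32
    decoder_layers: int = 2
    decoder_heads: int = 4
    mlp_ratio: int = 4
    pooling: str = "mean"  # "mean" over patch tokens, or "cls"
    learned_positions: bool = False
    standardize: bool = False  # per-channel standardization before encoding

    def __post_init__(self):
        counts = (
            self.image_size, self.patch_size, self.channels,
            self.encoder_dim, self.encoder_layers, self.encoder_heads,
            self.decoder_dim, self.decoder_layers, self.decoder_heads,
        )
        if any(int(c) != c or c <= 0 for c in counts):
            raise ConfigurationError("all model dimensions must be positive integers")
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.encoder_dim % self.encoder_heads or self.decoder_dim % self.decoder_heads:
            raise ConfigurationError("embedding dim must be divisible by head count")
        if self.pooling not in ("mean", "cls"):
            raise ConfigurationError("pooling must be 'mean' or 'cls'")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size**2

    @property
    def patch_dim(self) -> int:
        return self.patch_size**2 * self.channels

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Named presets. ``vit-large-mae`` mirrors the full-scale recipe (224 px
#: images, 16 px patches, 24 encoder / 8 decoder layers, 16 heads);
#: ``vit-tiny-test`` is the desk-scale model used throughout the test suite.
PRESETS: dict[str, ModelConfig] = {
    "vit-large-mae": ModelConfig(
        image_size=224, patch_size=16, channels=3,
        encoder_dim=1024, encoder_layers=24, encoder_heads=16,
        decoder_dim=512, decoder_layers=8, decoder_heads=16,
    ),
    "vit-tiny-test": ModelConfig(
        image_size=32, patch_size=4, channels=3,
        encoder_dim=64, encoder_layers=4, encoder_heads=4,
        decoder_dim=32, decoder_layers=2, decoder_heads=4,
        mlp_ratio=2,
    ),
}


@dataclasses.dataclass
class ImageBatch:
    """A batch of images, (batch, H, W, C), pixel values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 4:
            raise ConfigurationError("ImageBatch expects (batch, H, W, C)")
        if not np.all(np.isfinite(self.pixels)):
            raise ConfigurationError("pixel values must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ConfigurationError("pixel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    @property
    def channels(self) -> int:
        return self.pixels.shape[3]

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclasses.dataclass
class PatchSequence:
    """Row-major flattened patches, (batch, L, patch_size**2 * channels)."""

    patches: np.ndarray
    grid_rows: int
    grid_cols: int

    @property
    def num_patches(self) -> int:
        return self.grid_rows * self.grid_cols


def patchify(images: ImageBatch | np.ndarray, config: ModelConfig) -> PatchSequence:
    """Split images into non-overlapping patches, row-major, channels fastest."""
    px = images.pixels if isinstance(images, ImageBatch) else np.asarray(images)
    b, h, w, c = px.shape
    if h != config.image_size or w != config.image_size or c != config.channels:
        raise ConfigurationError(
            f"image shape {(h, w, c)} does not match config "
            f"({config.image_size}, {config.image_size}, {config.channels})"
        )
    p, g = config.patch_size, config.grid_size
    x = px.reshape(b, g, p, g, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # (b, gr, gc, p, p, c)
    return PatchSequence(x.reshape(b, g * g, p * p * c), g, g)


def unpatchify(patches: PatchSequence | np.ndarray, config: ModelConfig) -> ImageBatch:
    """Exact inverse of :func:`patchify`."""
    pt = patches.patches if isinstance(patches, PatchSequence) else np.asarray(patches)
    p, g = config.patch_size, config.grid_size
    if pt.ndim != 3 or pt.shape[1] != g * g or pt.shape[2] != config.patch_dim:
        raise ConfigurationError(
            f"patch array shape {pt.shape} inconsistent with config "
            f"(expected (*, {g * g}, {config.patch_dim}))"
        )
    b = pt.shape[0]
    x = pt.reshape(b, g, g, p, p, config.channels)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return ImageBatch(x.reshape(b, g * p, g * p, config.channels))


def sincos_positions(grid: int, dim: int) -> np.ndarray:
    """Fixed 2-D sine/cosine positional codes for a ``grid x grid`` layout."""
    if dim % 4 != 0:
        raise ConfigurationError("sincos positions require dim divisible by 4")
    half = dim // 2

    def axis_codes(positions: np.ndarray) -> np.ndarray:
        omega = 1.0 / 10000 ** (np.arange(half // 2, dtype=np.float64) / (half / 2.0))
        args = positions[:, None] * omega[None, :]
        return np.concatenate([np.sin(args), np.cos(args)], axis=1)

    rows, cols = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    emb = np.concatenate(
        [axis_codes(rows.reshape(-1).astype(np.float64)),
         axis_codes(cols.reshape(-1).astype(np.float64))],
        axis=1,
    )
    return emb.astype(np.float32)


def _init_linear(params, name, fan_in, fan_out, rng, std=None):
    std = std if std is not None else (2.0 / (fan_in + fan_out)) ** 0.5
    params[f"{name}.w"] = Tensor(
        rng.normal(0.0, std, size=(fan_in, fan_out)).astype(np.float32), requires_grad=True
    )
    params[f"{name}.b"] = Tensor(np.zeros(fan_out, dtype=np.float32), requires_grad=True)


def init_transformer_params(
    params: dict[str, Tensor], prefix: str, dim: int, layers: int, mlp_ratio: int,
    rng: np.random.Generator,
) -> None:
    for i in range(layers):
        p = f"{prefix}.block{i}"
        for ln in ("ln1", "ln2"):
            params[f"{p}.{ln}.g"] = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
            params[f"{p}.{ln}.b"] = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        _init_linear(params, f"{p}.qkv", dim, 3 * dim, rng, std=0.02)
        _init_linear(params, f"{p}.proj", dim, dim, rng, std=0.02)
        _init_linear(params, f"{p}.fc1", dim, mlp_ratio * dim, rng, std=0.02)
        _init_linear(params, f"{p}.fc2", mlp_ratio * dim, dim, rng, std=0.02)
    params[f"{prefix}.ln_out.g"] = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
    params[f"{prefix}.ln_out.b"] = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)


def transformer_forward(
    x: Tensor, params: dict[str, Tensor], prefix: str, layers: int, heads: int
) -> Tensor:
    """Pre-norm transformer stack over (batch, tokens, dim)."""
    for i in range(layers):
        p = f"{prefix}.block{i}"
        h = ad.layer_norm(x, params[f"{p}.ln1.g"], params[f"{p}.ln1.b"])
        qkv = ad.qkv_heads(
            ad.linear(h, params[f"{p}.qkv.w"], params[f"{p}.qkv.b"]), heads
        )
        att = ad.merge_heads(ad.attention_packed(qkv))
        x = ad.add(x, ad.linear(att, params[f"{p}.proj.w"], params[f"{p}.proj.b"]))
        h = ad.layer_norm(x, params[f"{p}.ln2.g"], params[f"{p}.ln2.b"])
        h = ad.gelu(ad.linear(h, params[f"{p}.fc1.w"], params[f"{p}.fc1.b"]))
        x = ad.add(x, ad.linear(h, params[f"{p}.fc2.w"], params[f"{p}.fc2.b"]))
    return ad.layer_norm(x, params[f"{prefix}.ln_out.g"], params[f"{prefix}.ln_out.b"])


class ViTEncoder:
    """ViT encoder over (possibly partial) patch sequences.

    One auxiliary class token is always prepended; whether it or the mean of
    the patch tokens forms the image embedding is controlled by
    ``config.pooling``.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, Tensor] = {}
        _init_linear(self.params, "enc.patch_embed", config.patch_dim, config.encoder_dim, rng)
        self.params["enc.cls"] = Tensor(
            rng.normal(0.0, 0.02, size=config.encoder_dim).astype(np.float32),
            requires_grad=True,
        )
        init_transformer_params(
            self.params, "enc", config.encoder_dim, config.encoder_layers,
            config.mlp_ratio, rng,
        )
        if config.learned_positions:
            self.params["enc.pos"] = Tensor(
                rng.normal(0.0, 0.02, size=(config.num_patches, config.encoder_dim))
                .astype(np.float32),
                requires_grad=True,
            )
            self._fixed_pos = None
        else:
            self._fixed_pos = sincos_positions(config.grid_size, config.encoder_dim)

    def _positions(self) -> np.ndarray | Tensor:
        if self._fixed_pos is not None:
            return self._fixed_pos
        return self.params["enc.pos"]

    def encode(self, patches: np.ndarray | PatchSequence, visible_idx: np.ndarray | None = None) -> Tensor:
        """Encode visible patches into per-token embeddings.

        Returns a (batch, 1 + n_visible, encoder_dim) tensor; token 0 is the
        class token, the rest follow the order of ``visible_idx``. Positional
        codes are looked up at each patch's original grid index before
        attention, so the encoder is consistent under reordering of
        ``visible_idx``.
        """
        pt = patches.patches if isinstance(patches, PatchSequence) else np.asarray(patches)
        cfg = self.config
        if pt.shape[1] != cfg.num_patches or pt.shape[2] != cfg.patch_dim:
            raise ConfigurationError(
                f"patch shape {pt.shape[1:]} does not match config "
                f"({cfg.num_patches}, {cfg.patch_dim})"
            )
        if visible_idx is None:
            visible_idx = np.arange(cfg.num_patches)
        visible_idx = np.asarray(visible_idx, dtype=np.int64)
        if visible_idx.size == 0:
            raise ConfigurationError("at least one patch must be visible")
        if np.unique(visible_idx).size != visible_idx.size:
            raise ConfigurationError("visible_idx contains duplicates")
        if visible_idx.min() < 0 or visible_idx.max() >= cfg.num_patches:
            raise ConfigurationError("visible_idx out of range")

        if cfg.standardize:
            # per-image, per-channel, so embeddings stay batch-composition invariant
            flat = pt.reshape(pt.shape[0], -1, cfg.channels)
            mu = flat.mean(axis=1, keepdims=True)
            sd = flat.std(axis=1, keepdims=True) + 1e-6
            pt = ((flat - mu) / sd).reshape(pt.shape)

        x = ad.linear(Tensor(pt[:, visible_idx]), self.params["enc.patch_embed.w"],
                      self.params["enc.patch_embed.b"])
        pos = self._positions()
        if isinstance(pos, Tensor):
            x = ad.add(x, ad.gather_tokens(ad.reshape(pos, (1,) + pos.shape), visible_idx))
        else:
            x = ad.add_const(x, pos[visible_idx])
        x = ad.prepend_token(x, self.params["enc.cls"])
        return transformer_forward(x, self.params, "enc", cfg.encoder_layers, cfg.encoder_heads)

    def embed_image(self, images: ImageBatch | np.ndarray) -> np.ndarray:
        """Fixed-length embedding per image from a full (unmasked) forward pass."""
        with ad.no_grad():
            tokens = self.encode(patchify(images, self.config)).data
        if self.config.pooling == "cls":
            return tokens[:, 0]
        return tokens[:, 1:].mean(axis=1)


def save_checkpoint(path: str | Path, params: dict[str, Tensor], config: ModelConfig) -> None:
    """Write weights as ``.npz`` with a sidecar ``.json`` capturing the config."""
    path = Path(path)
    np.savez(path, **{k: v.data for k, v in params.items()})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    """Load weights plus config; validates that the two agree."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = ModelConfig(**json.loads(sidecar.read_text()))
    with np.load(path) as data:
        weights = {k: data[k] for k in data.files}
    expected = weights["enc.patch_embed.w"].shape
    if expected != (config.patch_dim, config.encoder_dim):
        raise ConfigurationError(
            f"checkpoint weights {expected} disagree with sidecar config "
            f"({config.patch_dim}, {config.encoder_dim})"
        )
    return weights, config
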