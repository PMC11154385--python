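"""Masked autoencoding: random patch masking, decoding, reconstruction loss.

The autoencoder is asymmetric: the deep encoder sees only the visible
patches, while a lightweight decoder receives the projected visible-token
embeddings plus a learned mask token at every hidden position (each carrying
the positional code of its grid location) and predicts pixel content for all
patches. The training signal is the pixel-space mean squared error

    MSE = (1 / (W * H)) * sum_ij || s_hat_ij - s_ij ||_2^2,

where each pixel s_ij is a channel vector, averaged over the batch. With
``scope="full_image"`` the sum runs over every pixel; with
``scope="masked_only"`` both the sum and the normaliser are restricted to
pixels inside masked patches. When the reconstruction is composited (visible
patches passed through from the input) the two scopes agree up to the
normalising constant.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import (
    ConfigurationError,
    ImageBatch,
    ModelConfig,
    PatchSequence,
    ViTEncoder,
    init_transformer_params,
    load_checkpoint,
    patchify,
    save_checkpoint,
    sincos_positions,
    transformer_forward,
    _init_linear,
)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclasses.dataclass
class MaskSpec:
    """Per-patch boolean masking decision with an exact masked-count invariant."""

    masked: np.ndarray  # boolean, length L
    ratio: float
    seed_state: str = ""

    def __post_init__(self):
        self.masked = np.asarray(self.masked, dtype=bool)
        if self.masked.ndim != 1:
            raise ConfigurationError("MaskSpec.masked must be a 1-D boolean array")
        if not 0.0 <= self.ratio <= 1.0:
            raise ConfigurationError("mask ratio must lie in [0, 1]")
        expected = _round_half_away(self.ratio * self.masked.size)
        if int(self.masked.sum()) != expected:
            raise ConfigurationError(
                f"mask has {int(self.masked.sum())} masked patches, "
                f"expected round(ratio*L) = {expected}"
            )

    @property
    def num_patches(self) -> int:
        return self.masked.size

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())

    @property
    def masked_idx(self) -> np.ndarray:
        return np.flatnonzero(self.masked)

    @property
    def visible_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.masked)


def sample_mask(L: int, ratio: float, rng: np.random.Generator) -> MaskSpec:
    """Uniform random mask over ``L`` patches hiding exactly round(ratio*L).

    Masked indices are drawn uniformly without replacement; at least one
    patch must remain visible.
    """
    if L < 1:
        raise ConfigurationError("need at least one patch")
    if not 0.0 <= ratio <= 1.0:
        raise ConfigurationError("mask ratio must lie in [0, 1]")
    n_masked = _round_half_away(ratio * L)
    if n_masked >= L:
        raise ConfigurationError(
            f"ratio {ratio} would mask all {L} patches; at least one must stay visible"
        )
    masked = np.zeros(L, dtype=bool)
    masked[rng.choice(L, size=n_masked, replace=False)] = True
    return MaskSpec(masked=masked, ratio=ratio, seed_state=str(rng.bit_generator.state["state"]))


@dataclasses.dataclass
class Reconstruction:
    """Predicted images, same shape as the source batch.

    ``composited`` records whether visible patches were passed through
    verbatim from the input; predicted pixels are not clipped to [0, 1].
    """

    pixels: np.ndarray
    composited: bool


def _unpatchify_raw(patches: np.ndarray, config: ModelConfig) -> np.ndarray:
    p, g = config.patch_size, config.grid_size
    b = patches.shape[0]
    x = patches.reshape(b, g, g, p, p, config.channels)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(
        b, g * p, g * p, config.channels
    )


class MaskedAutoencoder:
    """ViT encoder plus lightweight reconstruction decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = ViTEncoder(config, rng)
        self.params = self.encoder.params  # decoder params share the dict
        _init_linear(self.params, "dec.embed", config.encoder_dim, config.decoder_dim, rng)
        self.params["dec.mask_token"] = Tensor(
            rng.normal(0.0, 0.02, size=config.decoder_dim).astype(np.float32),
            requires_grad=True,
        )
        init_transformer_params(
            self.params, "dec", config.decoder_dim, config.decoder_layers,
            config.mlp_ratio, rng,
        )
        _init_linear(self.params, "dec.pred", config.decoder_dim, config.patch_dim, rng)
        self._dec_pos = sincos_positions(config.grid_size, config.decoder_dim)

    @classmethod
    def from_preset(cls, name: str, seed: int = 0) -> "MaskedAutoencoder":
        from .backbone import PRESETS

        return cls(PRESETS[name], seed=seed)

    def copy(self) -> "MaskedAutoencoder":
        clone = MaskedAutoencoder(self.config, seed=0)
        clone.load_state({k: v.data for k, v in self.params.items()})
        return clone

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, weights: dict[str, np.ndarray]) -> None:
        if set(weights) != set(self.params):
            missing = set(self.params) ^ set(weights)
            raise ConfigurationError(f"weight names disagree with model: {sorted(missing)}")
        for k, v in weights.items():
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config)

    @classmethod
    def load(cls, path) -> "MaskedAutoencoder":
        weights, config = load_checkpoint(path)
        model = cls(config, seed=0)
        model.load_state(weights)
        return model

    # ----------------------------------------------------------- forward

    def predict_patches(self, patches: np.ndarray, mask: MaskSpec) -> Tensor:
        """Differentiable forward pass; returns predicted patches (B, L, P)."""
        cfg = self.config
        if mask.num_patches != cfg.num_patches:
            raise ConfigurationError(
                f"mask over {mask.num_patches} patches does not match model "
                f"with {cfg.num_patches}"
            )
        vis = mask.visible_idx
        tokens = self.encoder.encode(patches, vis)
        # drop the class token before decoding
        patch_tokens = ad.gather_tokens(tokens, np.arange(1, tokens.data.shape[1]))
        x = ad.linear(patch_tokens, self.params["dec.embed.w"], self.params["dec.embed.b"])
        x = ad.assemble_tokens(x, self.params["dec.mask_token"], vis, cfg.num_patches)
        x = ad.add_const(x, self._dec_pos)
        x = transformer_forward(x, self.params, "dec", cfg.decoder_layers, cfg.decoder_heads)
        return ad.linear(x, self.params["dec.pred.w"], self.params["dec.pred.b"])

    def forward_reconstruct(
        self, images: ImageBatch | np.ndarray, mask: MaskSpec, composited: bool = True
    ) -> Reconstruction:
        """Reconstruct a masked batch into image space (no gradient tape)."""
        seq = patchify(images, self.config)
        with ad.no_grad():
            pred = self.predict_patches(seq.patches, mask).data
        if composited:
            pred = pred.copy()
            pred[:, mask.visible_idx] = seq.patches[:, mask.visible_idx]
        return Reconstruction(
            pixels=_unpatchify_raw(pred, self.config), composited=composited
        )

    def training_loss(
        self,
        patches: np.ndarray,
        mask: MaskSpec,
        scope: str = "full_image",
        composited: bool = True,
    ) -> Tensor:
        """Differentiable reconstruction loss on a patchified batch.

        With ``composited=True`` visible patches contribute zero error (they
        would be passed through from the input), so only masked patches enter
        the sum; the two scopes then differ only in the normaliser.
        """
        pred = self.predict_patches(patches, mask)
        cfg = self.config
        b = patches.shape[0]
        area = cfg.image_size * cfg.image_size
        if scope == "full_image":
            weight = (
                mask.masked.astype(np.float32)[None, :, None]
                if composited
                else np.float32(1.0)
            )
            normalizer = float(b * area)
        elif scope == "masked_only":
            weight = mask.masked.astype(np.float32)[None, :, None]
            normalizer = float(b * mask.n_masked * cfg.patch_size**2)
        else:
            raise ConfigurationError("scope must be 'full_image' or 'masked_only'")
        return ad.weighted_sq_error(pred, patches, weight, normalizer)


def reconstruction_loss(
    recon: Reconstruction | np.ndarray,
    target: ImageBatch | np.ndarray,
    mask: MaskSpec,
    scope: str = "full_image",
) -> float:
    """Pixel-space mean squared reconstruction error.

    ``full_image``: sum of squared channel-vector differences over all pixels,
    divided by W*H and averaged over the batch. ``masked_only``: the sum and
    the normaliser are restricted to pixels inside masked patches.
    """
    rp = recon.pixels if isinstance(recon, Reconstruction) else np.asarray(recon)
    tp = target.pixels if isinstance(target, ImageBatch) else np.asarray(target)
    if rp.shape != tp.shape:
        raise ConfigurationError(f"shape mismatch: {rp.shape} vs {tp.shape}")
    b, h, w, _ = rp.shape
    diff2 = (rp.astype(np.float64) - tp.astype(np.float64)) ** 2
    if scope == "full_image":
        return float(diff2.sum() / (b * w * h))
    if scope != "masked_only":
        raise ConfigurationError("scope must be 'full_image' or 'masked_only'")
    grid = math.isqrt(mask.num_patches)
    if grid * grid != mask.num_patches or h % grid != 0:
        raise ConfigurationError("mask length incompatible with image size")
    p = h // grid
    pix = mask.masked.reshape(grid, grid).repeat(p, axis=0).repeat(p, axis=1)
    n_pix = mask.n_masked * p * p
    if n_pix == 0:
        raise ConfigurationError("masked_only scope needs at least one masked patch")
    return float(diff2[:, pix, :].sum() / (b * n_pix))


def save_reconstruction_grid(
    images: ImageBatch,
    mask: MaskSpec,
    recon: Reconstruction,
    path: str | Path,
    max_images: int = 8,
) -> None:
    """Dump an (input / masked input / reconstruction) PNG grid for inspection."""
    from PIL import Image

    n = min(len(images), max_images)
    h, w = images.height, images.width
    grid = math.isqrt(mask.num_patches)
    p = h // grid
    pix = mask.masked.reshape(grid, grid).repeat(p, axis=0).repeat(p, axis=1)
    rows = []
    for i in range(n):
        masked_img = images.pixels[i].copy()
        masked_img[pix] = 0.5
        row = np.concatenate(
            [images.pixels[i], masked_img, np.clip(recon.pixels[i], 0, 1)], axis=1
        )
        rows.append(row)
    canvas = (np.concatenate(rows, axis=0) * 255).astype(np.uint8)
    Image.fromarray(canvas).save(Path(path))
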