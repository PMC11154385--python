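"""Procedural multi-domain image collections for desk-scale experiments.

Four image families with genuinely different spatial statistics stand in for
visually distinct acquisition domains (satellite tiles, dermoscopy, blood
smears, ...): oriented Gabor-like gratings, blob constellations, concentric
rings and warped checkerboards. Within a family, each class occupies a
distinct mode of a scalar generative parameter (grating orientation, ring
radius of the constellation, radial frequency, checker frequency); class
means are spaced ``class_separation`` parameter units apart, per-image
jitter and additive pixel noise blur the modes, and every image receives a
random per-channel tint so the three channels are informative.

What this emulates is only the statistical shape of a cross-domain few-shot
benchmark — multiple separable classes inside each of several mutually
dissimilar domains — not the appearance of any real modality.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .backbone import ConfigurationError
from .episodes import LabelledImage

FAMILIES = ("gabor_textures", "blob_constellations", "concentric_rings", "checker_warp")

#: per-image jitter of the class parameter, in the same units as
#: ``class_separation`` (so separation directly controls mode overlap)
_PARAM_JITTER_SD = 0.15
_TINT_SD = 0.06


@dataclasses.dataclass(frozen=True)
class DomainSpec:
    family: str
    n_classes: int = 8
    images_per_class: int = 12
    image_size: int = 32
    class_separation: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_classes < 2 or self.images_per_class < 1:
            raise ConfigurationError("need n_classes >= 2 and images_per_class >= 1")
        if self.class_separation <= 0:
            raise ConfigurationError("class_separation must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    ax = (np.arange(size) + 0.5) / size - 0.5
    return np.meshgrid(ax, ax, indexing="ij")


def _gabor(size: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    v, u = _grid(size)
    freq = 3.0 + rng.normal(0.0, 0.2)
    phase = rng.uniform(0.0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * (u * np.cos(theta) + v * np.sin(theta)) + phase)
    return 0.5 + 0.4 * wave


def _blobs(size: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v, u = _grid(size)
    img = np.zeros((size, size))
    n_blobs = 5
    base_angle = rng.uniform(0.0, 2 * np.pi)
    for b in range(n_blobs):
        ang = base_angle + 2 * np.pi * b / n_blobs + rng.normal(0.0, 0.08)
        r = max(0.02, radius + rng.normal(0.0, 0.015))
        cy, cx = r * np.sin(ang), r * np.cos(ang)
        sigma = 0.05 + rng.normal(0.0, 0.005)
        img += np.exp(-((u - cx) ** 2 + (v - cy) ** 2) / (2 * sigma**2))
    return np.clip(0.1 + 0.8 * img / img.max(), 0.0, 1.0)


def _rings(size: int, freq: float, rng: np.random.Generator) -> np.ndarray:
    v, u = _grid(size)
    r = np.sqrt(u**2 + v**2)
    # moderate phase jitter: full-circle phase would decorrelate same-class
    # images in pixel space and erase the class modes
    phase = rng.normal(0.0, 0.5)
    return 0.5 + 0.4 * np.sin(2 * np.pi * freq * r + phase)


def _checker(size: int, freq: float, rng: np.random.Generator) -> np.ndarray:
    v, u = _grid(size)
    amp = 0.08 + rng.normal(0.0, 0.01)
    warp = rng.uniform(1.5, 2.5)
    uw = u + amp * np.sin(2 * np.pi * warp * v)
    vw = v + amp * np.sin(2 * np.pi * warp * u)
    return 0.5 + 0.4 * np.sign(np.sin(2 * np.pi * freq * uw) * np.sin(2 * np.pi * freq * vw))


def _class_parameter(family: str, class_index: int, separation: float) -> float:
    """Mean of the per-class generative parameter, in family-specific units."""
    if family == "gabor_textures":
        return 0.2 * separation * class_index  # orientation, radians
    if family == "blob_constellations":
        return min(0.45, 0.10 + 0.05 * separation * class_index)  # ring radius
    if family == "concentric_rings":
        return 2.0 + 0.8 * separation * class_index  # radial frequency
    return 1.5 + 0.5 * separation * class_index  # checker frequency


_RENDER = {
    "gabor_textures": (_gabor, 0.2),
    "blob_constellations": (_blobs, 0.05),
    "concentric_rings": (_rings, 0.8),
    "checker_warp": (_checker, 0.5),
}


def make_domain(spec: DomainSpec) -> list[LabelledImage]:
    """Render a labelled collection: ``n_classes * images_per_class`` RGB images.

    Fully reproducible from ``spec.seed``; label balance is exact; pixel
    values are clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    render, unit = _RENDER[spec.family]
    out: list[LabelledImage] = []
    domain = spec.name or spec.family
    for cls in range(spec.n_classes):
        mean_param = _class_parameter(spec.family, cls, spec.class_separation)
        for _ in range(spec.images_per_class):
            param = mean_param + rng.normal(0.0, _PARAM_JITTER_SD) * unit
            if spec.family == "blob_constellations":
                param = float(np.clip(param, 0.03, 0.47))
            gray = render(spec.image_size, param, rng)
            tint = 1.0 + rng.normal(0.0, _TINT_SD, size=3)
            img = gray[:, :, None] * tint[None, None, :]
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            out.append(
                LabelledImage(
                    image=np.clip(img, 0.0, 1.0).astype(np.float32),
                    label=cls,
                    domain=domain,
                )
            )
    return out


@dataclasses.dataclass(frozen=True)
class BenchmarkSizes:
    """Collection sizes for the pretrain/episodic benchmark split."""

    source_classes: int = 6
    source_images_per_class: int = 20
    target_classes: int = 8
    target_images_per_class: int = 12
    image_size: int = 32
    class_separation: float = 1.0
    noise_sd: float = 0.05


def make_benchmark(
    source_families: Sequence[str],
    target_family: str,
    sizes: BenchmarkSizes | None = None,
    seed: int = 0,
) -> tuple[list[LabelledImage], list[LabelledImage]]:
    """Pooled source collection (for pretraining) + disjoint-family target.

    The target family must not appear among the sources: episodes drawn from
    the target are then out-of-domain with respect to pretraining by
    construction. Source labels are namespaced per family; they are present
    but unused by the self-supervised pretraining path.
    """
    if not source_families:
        raise ConfigurationError("need at least one source family")
    if target_family in source_families:
        raise ConfigurationError(
            f"target family {target_family!r} overlaps the source families"
        )
    sizes = sizes or BenchmarkSizes()
    seeds = np.random.SeedSequence(seed).generate_state(len(source_families) + 1)
    pretrain: list[LabelledImage] = []
    for fam, fam_seed in zip(source_families, seeds[:-1]):
        domain = make_domain(
            DomainSpec(
                family=fam,
                n_classes=sizes.source_classes,
                images_per_class=sizes.source_images_per_class,
                image_size=sizes.image_size,
                class_separation=sizes.class_separation,
                noise_sd=sizes.noise_sd,
                seed=int(fam_seed % 2**31),
            )
        )
        for item in domain:
            item.label = f"{fam}/{item.label}"
        pretrain.extend(domain)
    target = make_domain(
        DomainSpec(
            family=target_family,
            n_classes=sizes.target_classes,
            images_per_class=sizes.target_images_per_class,
            image_size=sizes.image_size,
            class_separation=sizes.class_separation,
            noise_sd=sizes.noise_sd,
            seed=int(seeds[-1] % 2**31),
        )
    )
    return pretrain, target


def export_image_folder(collection: Sequence[LabelledImage], root: str | Path) -> None:
    """Write a collection as a class-per-subdirectory PNG folder."""
    from PIL import Image

    root = Path(root)
    counters: dict = {}
    for item in collection:
        cls_dir = root / str(item.label).replace("/", "_")
        cls_dir.mkdir(parents=True, exist_ok=True)
        i = counters.get(item.label, 0)
        counters[item.label] = i + 1
        arr = (np.clip(item.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(cls_dir / f"{i:04d}.png")
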