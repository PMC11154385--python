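"""N-way K-shot episodic batch construction over labelled image collections.

An episode is a self-contained few-shot task: ``w`` classes are sampled from
the collection, then ``k + q`` distinct images per class, partitioned into a
labelled support set S (n = w*k images) and a query set Q (m = w*q images).
Sampling is without replacement within an episode and with replacement
across episodes.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .backbone import ConfigurationError


@dataclasses.dataclass
class LabelledImage:
    """A single image (H, W, C in [0, 1]) with its class label and source domain."""

    image: np.ndarray
    label: int | str
    domain: str = ""
    path: str = ""


@dataclasses.dataclass(frozen=True)
class EpisodeSpec:
    """Episode shape: ``ways`` classes, ``shots`` support and ``queries`` query
    images per class. Table-style totals (queries as an episode-wide count) are
    available with ``queries_total=True``."""

    ways: int = 5
    shots: int = 5
    queries: int = 15
    queries_total: bool = False

    def __post_init__(self):
        if self.ways < 2 or self.shots < 1 or self.queries < 1:
            raise ConfigurationError("need ways >= 2, shots >= 1, queries >= 1")
        if self.queries_total and self.queries % self.ways != 0:
            raise ConfigurationError("total query count must divide evenly across ways")

    @property
    def queries_per_class(self) -> int:
        return self.queries // self.ways if self.queries_total else self.queries


@dataclasses.dataclass
class Episode:
    """Support/query split with way/shot bookkeeping."""

    support: list[LabelledImage]
    query: list[LabelledImage]
    label_set: list

    @property
    def ways(self) -> int:
        return len(self.label_set)

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def n_query(self) -> int:
        return len(self.query)

    def support_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(images, integer labels indexed into label_set) for the support set."""
        return self._arrays(self.support)

    def query_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._arrays(self.query)

    def _arrays(self, items: list[LabelledImage]) -> tuple[np.ndarray, np.ndarray]:
        index = {lab: i for i, lab in enumerate(self.label_set)}
        images = np.stack([it.image for it in items]).astype(np.float32)
        labels = np.array([index[it.label] for it in items], dtype=np.int64)
        return images, labels


def _by_class(collection: Sequence[LabelledImage]) -> dict:
    groups: dict = defaultdict(list)
    for i, item in enumerate(collection):
        groups[item.label].append(i)
    return groups


def sample_episode(
    collection: Sequence[LabelledImage],
    spec: EpisodeSpec,
    rng: np.random.Generator,
) -> Episode:
    """Sample one episode uniformly: w classes, then k+q distinct images each."""
    groups = _by_class(collection)
    labels = sorted(groups)  # lexicographic for determinism
    if len(labels) < spec.ways:
        raise ConfigurationError(
            f"collection has {len(labels)} classes, episode needs {spec.ways}"
        )
    q = spec.queries_per_class
    need = spec.shots + q
    for lab in labels:
        if len(groups[lab]) < need:
            raise ConfigurationError(
                f"class {lab!r} has {len(groups[lab])} images, episode needs {need}"
            )
    chosen = [labels[i] for i in rng.choice(len(labels), size=spec.ways, replace=False)]
    support: list[LabelledImage] = []
    query: list[LabelledImage] = []
    for lab in chosen:
        idx = rng.choice(len(groups[lab]), size=need, replace=False)
        picks = [collection[groups[lab][i]] for i in idx]
        support.extend(picks[: spec.shots])
        query.extend(picks[spec.shots :])
    return Episode(support=support, query=query, label_set=chosen)


def episode_stream(
    collection: Sequence[LabelledImage],
    spec: EpisodeSpec,
    n_episodes: int,
    seed: int,
) -> Iterator[Episode]:
    """Deterministic sequence of independent episodes from a seed."""
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_episodes):
        yield sample_episode(collection, spec, np.random.default_rng(child))


def load_image_folder(
    root: str | Path,
    image_size: int,
    resize_mode: str = "squash",
    domain: str | None = None,
) -> list[LabelledImage]:
    """Read a class-per-subdirectory image folder (``root/class_name/*.png|jpg``).

    Images are converted to RGB and brought to ``image_size`` square, either
    by squash-resize (default) or center-crop-then-resize, with bilinear
    interpolation. Class labels are the subdirectory names; their mapping to
    integer indices elsewhere is lexicographic.
    """
    from PIL import Image

    root = Path(root)
    if resize_mode not in ("squash", "center_crop"):
        raise ConfigurationError("resize_mode must be 'squash' or 'center_crop'")
    items: list[LabelledImage] = []
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ConfigurationError(f"no class subdirectories under {root}")
    for cls in classes:
        files = sorted(
            f for f in (root / cls).iterdir()
            if f.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        for f in files:
            with Image.open(f) as im:
                im = im.convert("RGB")
                if resize_mode == "center_crop":
                    side = min(im.size)
                    left = (im.width - side) // 2
                    top = (im.height - side) // 2
                    im = im.crop((left, top, left + side, top + side))
                im = im.resize((image_size, image_size), Image.BILINEAR)
                arr = np.asarray(im, dtype=np.float32) / 255.0
            items.append(
                LabelledImage(image=arr, label=cls, domain=domain or root.name, path=str(f))
            )
    return items


def export_manifest(episode: Episode, path: str | Path) -> None:
    """Write a JSON audit manifest of an episode (paths, labels, roles)."""
    payload = {
        "label_set": [str(lab) for lab in episode.label_set],
        "support": [
            {"label": str(it.label), "domain": it.domain, "path": it.path}
            for it in episode.support
        ],
        "query": [
            {"label": str(it.label), "domain": it.domain, "path": it.path}
            for it in episode.query
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
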