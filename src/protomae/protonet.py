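"""Prototype (nearest-centroid) classification of embedded episodes.

Each class prototype is the arithmetic mean of its support embeddings; a
query is assigned to the class whose prototype is nearest under the
configured metric (Euclidean by default, cosine optionally). Under cosine,
embeddings and centroids are L2-normalised; under Euclidean they are used
as-is. Ties break deterministically toward the lowest class index.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .backbone import ConfigurationError


@dataclasses.dataclass
class Prototypes:
    centroids: np.ndarray  # (w, dim)
    class_ids: list
    metric: str = "euclidean"

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] != len(self.class_ids):
            raise ConfigurationError("need one centroid per class")
        if not np.all(np.isfinite(self.centroids)):
            raise ConfigurationError("centroids must be finite")
        if self.metric not in ("euclidean", "cosine"):
            raise ConfigurationError("metric must be 'euclidean' or 'cosine'")


def compute_centroids(
    support_embeddings: np.ndarray,
    support_labels: np.ndarray,
    metric: str = "euclidean",
) -> Prototypes:
    """Mean support embedding per class, ordered by sorted class id."""
    emb = np.asarray(support_embeddings, dtype=np.float64)
    labels = np.asarray(support_labels)
    if emb.ndim != 2 or emb.shape[0] != labels.shape[0]:
        raise ConfigurationError("one label per support embedding required")
    class_ids = sorted(set(labels.tolist()))
    if metric == "cosine":
        emb = emb / (np.linalg.norm(emb, axis=1, keepdims=True) + 1e-12)
    centroids = []
    for cid in class_ids:
        members = emb[labels == cid]
        if members.shape[0] == 0:
            raise ConfigurationError(f"class {cid!r} has no support embeddings")
        centroids.append(members.mean(axis=0))
    return Prototypes(np.stack(centroids), class_ids, metric)


def classify(query_embeddings: np.ndarray, prototypes: Prototypes) -> np.ndarray:
    """Nearest-centroid label per query (ties -> lowest class index)."""
    q = np.asarray(query_embeddings, dtype=np.float64)
    if q.ndim != 2 or q.shape[1] != prototypes.centroids.shape[1]:
        raise ConfigurationError(
            f"query dim {q.shape} does not match centroid dim "
            f"{prototypes.centroids.shape}"
        )
    c = prototypes.centroids
    if prototypes.metric == "cosine":
        q = q / (np.linalg.norm(q, axis=1, keepdims=True) + 1e-12)
        c = c / (np.linalg.norm(c, axis=1, keepdims=True) + 1e-12)
        dist = 1.0 - q @ c.T
    else:
        dist = ((q[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    picks = dist.argmin(axis=1)  # argmin takes the first (lowest) index on ties
    return np.array([prototypes.class_ids[i] for i in picks])


def episode_accuracy(predictions: np.ndarray, true_labels: np.ndarray) -> float:
    """Fraction of queries classified correctly."""
    preds = np.asarray(predictions)
    truth = np.asarray(true_labels)
    if preds.shape != truth.shape:
        raise ConfigurationError("predictions and labels must align")
    if preds.size == 0:
        raise ConfigurationError("empty query set")
    return float((preds == truth).mean())


def confusion_matrix(predictions: np.ndarray, true_labels: np.ndarray, class_ids: list) -> np.ndarray:
    """Per-episode confusion counts (rows: truth, cols: prediction)."""
    index = {cid: i for i, cid in enumerate(class_ids)}
    out = np.zeros((len(class_ids), len(class_ids)), dtype=np.int64)
    for p, t in zip(np.asarray(predictions), np.asarray(true_labels)):
        out[index[t], index[p]] += 1
    return out


def save_confusion_csv(matrix: np.ndarray, class_ids: list, path) -> None:
    """Write a confusion matrix as CSV with class ids as header and row names."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["truth\\pred"] + [str(c) for c in class_ids])
        for cid, row in zip(class_ids, np.asarray(matrix)):
            writer.writerow([str(cid)] + [int(v) for v in row])
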