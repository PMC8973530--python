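"""Out-of-sample re-embedding through a fitted manifold model.

A new vector x is attached to the training window by its k nearest training
points, reconstructed as an affine (sum-to-one) combination of them with the
same regularized weight rule used at fit time — weights outside the
neighborhood are zero — and mapped as y = sum_j w_j y_j, the closed-form
single-point minimizer of the embedding cost.  The map is therefore exactly
linear in Y_train and translation-equivariant.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .embeddings import WordEmbeddingSet
from .mlle import ManifoldModel, regularized_weights

logger = logging.getLogger("wordmanifold")

__all__ = ["ReembedResult", "transform", "transform_many", "reembed_vocabulary", "handle_oov"]


@dataclass
class ReembedResult:
    """A vocabulary re-embedded through a fitted model."""

    source: WordEmbeddingSet
    target: WordEmbeddingSet
    reused_words: list[str]       # training-window words passed through
    provenance: dict = field(default_factory=dict)


def _oos_neighbors(model: ManifoldModel, x: np.ndarray, k_oos: int, metric: str):
    diffs = model.X_train - x
    dist = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    if metric == "euclidean":
        return np.argsort(dist, kind="stable")[:k_oos]
    if metric == "geodesic":
        # experimental: attach x to the training graph through its Euclidean
        # nearest neighbors, rank by attachment + in-graph geodesic
        if model.graph is None or model.graph.geodesic is None:
            raise ValueError(
                "geodesic out-of-sample ranking needs a model fitted with "
                "keep_graph=True and the normalized_geodesic metric"
            )
        anchors = np.argsort(dist, kind="stable")[: model.graph.k_graph]
        attached = np.min(
            dist[anchors][:, None] + model.graph.geodesic[anchors], axis=0
        )
        return np.argsort(attached, kind="stable")[:k_oos]
    raise ValueError(f"unknown out-of-sample metric {metric!r}")


def transform(
    model: ManifoldModel,
    x: np.ndarray,
    k_oos: int | None = None,
    metric: str = "euclidean",
    return_weights: bool = False,
):
    """Embed a single D-vector through the fitted model.

    Returns the d-dimensional coordinate, or ``(y, weights, neighbors)``
    when ``return_weights`` is set.  ``k_oos`` defaults to the model's k.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.dim,):
        raise ValueError(f"expected a vector of length {model.dim}, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector contains NaN or Inf")
    k_oos = model.k if k_oos is None else int(k_oos)
    if not 1 <= k_oos <= model.n:
        raise ValueError(f"need 1 <= k_oos <= window size {model.n}, got {k_oos}")
    idx = _oos_neighbors(model, x, k_oos, metric)
    C = model.X_train[idx] - x
    G = C @ C.T
    w = regularized_weights(G, model.gamma_scale)
    y = w @ model.Y_train[idx]
    if return_weights:
        return y, w, idx
    return y


def transform_many(
    model: ManifoldModel,
    X: np.ndarray,
    k_oos: int | None = None,
    metric: str = "euclidean",
) -> np.ndarray:
    """Vectorized :func:`transform` over the rows of X."""
    X = np.asarray(X, dtype=np.float64)
    out = np.empty((X.shape[0], model.d))
    for i in range(X.shape[0]):
        out[i] = transform(model, X[i], k_oos=k_oos, metric=metric)
    return out


def reembed_vocabulary(
    model: ManifoldModel,
    emb: WordEmbeddingSet,
    k_oos: int | None = None,
    metric: str = "euclidean",
    reuse_training: bool = True,
) -> ReembedResult:
    """Re-embed every word of ``emb`` into the model's manifold coordinates.

    Words that belong to the training window are passed through to their
    fitted coordinates by default (exact idempotence on the window); set
    ``reuse_training=False`` to re-transform them like any other vector.
    """
    if emb.dim != model.dim:
        raise ValueError(
            f"embedding dimension {emb.dim} != model input dimension {model.dim}"
        )
    train_row = {w: i for i, w in enumerate(model.vocab)} if model.vocab else {}
    target = np.empty((emb.n, model.d))
    reused = []
    for i, word in enumerate(emb.vocab):
        j = train_row.get(word) if reuse_training else None
        if j is not None:
            target[i] = model.Y_train[j]
            reused.append(word)
        else:
            target[i] = transform(model, emb.vectors[i], k_oos=k_oos, metric=metric)
    out = WordEmbeddingSet(
        vocab=list(emb.vocab), vectors=target, rank=emb.rank.copy()
    )
    return ReembedResult(
        source=emb,
        target=out,
        reused_words=reused,
        provenance={
            "window_start": model.window_start,
            "window_size": model.n,
            "k": model.k,
            "d": model.d,
            "k_oos": model.k if k_oos is None else int(k_oos),
            "metric": model.metric,
            "oos_metric": metric,
            "reuse_training": reuse_training,
        },
    )


def handle_oov(word: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic random vector for an out-of-vocabulary word.

    Components are i.i.d. uniform on [-0.5/dim, 0.5/dim] — the usual random
    initialization by dimension size — drawn from a generator keyed on
    (seed, hash(word)), so the same word and seed always yield the same
    vector while different words get independent draws.
    """
    if dim <= 0:
        raise ValueError("dim must be positive")
    digest = hashlib.md5(word.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, key])
    return rng.uniform(-0.5 / dim, 0.5 / dim, size=dim)
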