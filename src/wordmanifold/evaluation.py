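"""Intrinsic evaluation: word-pair similarity against human ratings.

Candidate embeddings are scored by the cosine similarity of each rated word
pair, then correlated with the human ratings — Pearson for linear agreement,
Spearman (mid-rank) for monotone agreement.  Multiword medical terms
("pulmonary edema") are vectorized as the mean of their in-vocabulary
tokens; pairs with unresolvable terms are skipped (or given seeded random
vectors, matching the downstream-task convention).

Both correlation coefficients are computed from first principles here; the
test suite cross-checks them against an independent statistics library.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embeddings import WordEmbeddingSet
from .reembed import handle_oov

__all__ = [
    "SimilarityDataset",
    "EvalResult",
    "SKIP",
    "load_similarity_csv",
    "save_similarity_csv",
    "term_vector",
    "cosine_similarity",
    "pearson",
    "spearman",
    "midranks",
    "evaluate",
]


class _Skip:
    def __repr__(self) -> str:  # pragma: no cover
        return "SKIP"


#: Sentinel returned by :func:`term_vector` when a term cannot be resolved.
SKIP = _Skip()


@dataclass
class SimilarityDataset:
    """Word pairs with human similarity/relatedness ratings."""

    pairs: list[tuple[str, str, float]]
    name: str = "similarity"
    scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for t1, t2, r in self.pairs:
            key = (t1, t2)
            if key in seen:
                raise ValueError(f"duplicate pair {key!r} in dataset {self.name!r}")
            seen.add(key)
            if self.scale is not None and not (self.scale[0] <= r <= self.scale[1]):
                raise ValueError(
                    f"rating {r} for {key!r} outside scale {self.scale}"
                )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EvalResult:
    """Correlation of an embedding's cosine scores with human ratings."""

    pearson: float
    spearman: float
    n_scored: int
    n_skipped: int
    name: str = ""

    def as_tsv_row(self) -> str:
        return (
            f"{self.name}\t{self.n_scored}\t{self.n_skipped}"
            f"\t{self.pearson:.6f}\t{self.spearman:.6f}"
        )


def load_similarity_csv(path: str | Path, name: str | None = None) -> SimilarityDataset:
    """Read a ``term1,term2,rating`` CSV; a non-numeric first row is a header."""
    path = Path(path)
    pairs: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, 1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(row)}")
            t1, t2, raw = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                rating = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric rating {raw!r}"
                ) from None
            pairs.append((t1, t2, rating))
    if not pairs:
        raise ValueError(f"{path}: no data rows")
    return SimilarityDataset(pairs=pairs, name=name or path.stem)


def save_similarity_csv(ds: SimilarityDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term1", "term2", "rating"])
        for t1, t2, r in ds.pairs:
            writer.writerow([t1, t2, repr(r)])


def term_vector(
    emb: WordEmbeddingSet,
    term: str,
    oov_policy: str = "skip",
    seed: int = 0,
):
    """Vector for a possibly multiword term, or :data:`SKIP`.

    A multiword term is the mean of its in-vocabulary token vectors; if no
    token is in vocabulary the OOV policy decides: ``"skip"`` returns SKIP,
    ``"random_seeded"`` a deterministic random vector.
    """
    if not term.strip():
        raise ValueError("empty term")
    if oov_policy not in ("skip", "random_seeded"):
        raise ValueError(f"unknown oov_policy {oov_policy!r}")
    vec = emb.get(term)
    if vec is not None:
        return vec
    tokens = term.split()
    present = [emb.get(t) for t in tokens]
    present = [v for v in present if v is not None]
    if present:
        return np.mean(present, axis=0)
    if oov_policy == "skip":
        return SKIP
    return handle_oov(term, emb.dim, seed)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(dx @ dx)
    sy = np.sqrt(dy @ dy)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.clip(dx @ dy / (sx * sy), -1.0, 1.0))


def midranks(x) -> np.ndarray:
    """Ranks 1..n with ties assigned their average (mid) rank."""
    x = np.asarray(x, dtype=np.float64)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    return pearson(midranks(x), midranks(y))


def evaluate(
    emb: WordEmbeddingSet,
    ds: SimilarityDataset,
    oov_policy: str = "skip",
    seed: int = 0,
) -> EvalResult:
    """Score every resolvable pair by cosine similarity and correlate.

    Pairs whose terms cannot be resolved under the OOV policy are counted in
    ``n_skipped``, never scored.  Fails if fewer than 3 pairs are scorable.
    """
    scores, ratings = [], []
    n_skipped = 0
    for t1, t2, rating in ds.pairs:
        v1 = term_vector(emb, t1, oov_policy, seed)
        v2 = term_vector(emb, t2, oov_policy, seed)
        if v1 is SKIP or v2 is SKIP:
            n_skipped += 1
            continue
        scores.append(cosine_similarity(v1, v2))
        ratings.append(rating)
    if len(scores) < 3:
        raise ValueError(
            f"only {len(scores)} of {len(ds)} pairs scorable in dataset "
            f"{ds.name!r}; need at least 3"
        )
    return EvalResult(
        pearson=pearson(scores, ratings),
        spearman=spearman(scores, ratings),
        n_scored=len(scores),
        n_skipped=n_skipped,
        name=ds.name,
    )
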