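"""Synthetic fixtures with the statistical structure the method assumes.

Real word vectors are believed to lie near a curved low-dimensional manifold
inside a high-dimensional ambient space; frequency-sorted vocabularies put
the best manifold samples first; and human similarity ratings are monotone
in semantic (geodesic) proximity.  The generators here reproduce exactly
those three features so the full pipeline is testable without downloads:

* points on a swiss roll, S-curve or linear subspace, lifted into the
  ambient dimension by a random orthogonal map, plus isotropic noise;
* a Zipf-distributed frequency side file;
* a gold similarity dataset whose ratings decay exponentially with latent
  distance.

Both curved surfaces are arc-length parametrized, so Euclidean distance in
latent coordinates *is* geodesic distance along the manifold — the gold
ratings are genuinely monotone in geodesic proximity, not merely in the
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import WordEmbeddingSet
from .evaluation import SimilarityDataset

__all__ = [
    "SyntheticManifoldSpec",
    "generate_manifold_embeddings",
    "generate_similarity_gold",
    "generate_zipf_frequencies",
]

MANIFOLDS = ("swiss_roll", "s_curve", "linear_subspace")


@dataclass
class SyntheticManifoldSpec:
    """Conditions for one synthetic embedding set.

    Defaults are the package's standard benchmark: 1500 words near a 2-d
    swiss roll in 100 ambient dimensions with noise 0.05.
    """

    n_words: int = 1500
    latent_dim: int = 2
    ambient_dim: int = 100
    manifold: str = "swiss_roll"
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.manifold not in MANIFOLDS:
            raise ValueError(f"unknown manifold {self.manifold!r}; choose from {MANIFOLDS}")
        if self.manifold in ("swiss_roll", "s_curve") and self.latent_dim != 2:
            raise ValueError(f"{self.manifold} is a 2-d surface; latent_dim must be 2")
        if not self.latent_dim < self.ambient_dim:
            raise ValueError("latent_dim must be smaller than ambient_dim")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_words < 10:
            raise ValueError("n_words must be >= 10")


def _swiss_roll(rng: np.random.Generator, n: int):
    """Swiss roll (t cos t, t sin t, h), sampled uniformly by arc length.

    The latent coordinates are (arc length along the spiral, height), an
    isometric parametrization of the surface.
    """
    t_min, t_max = 1.5 * np.pi, 4.5 * np.pi
    tgrid = np.linspace(t_min, t_max, 20000)
    speed = np.sqrt(1.0 + tgrid**2)
    sgrid = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(tgrid))]
    )
    u = rng.uniform(0.0, sgrid[-1], n)
    t = np.interp(u, sgrid, tgrid)
    h = rng.uniform(0.0, 21.0, n)
    base = np.column_stack([t * np.cos(t), t * np.sin(t), h])
    latent = np.column_stack([u, h])
    return base, latent


def _s_curve(rng: np.random.Generator, n: int):
    """S-curve (sin t, h, sign(t)(cos t - 1)); t is already arc length."""
    t = rng.uniform(-1.5 * np.pi, 1.5 * np.pi, n)
    h = rng.uniform(0.0, 2.0, n)
    base = np.column_stack([np.sin(t), h, np.sign(t) * (np.cos(t) - 1.0)])
    latent = np.column_stack([t, h])
    return base, latent


def generate_manifold_embeddings(spec: SyntheticManifoldSpec):
    """Sample word vectors near a manifold; return (embeddings, latent).

    Latent points are mapped onto the surface, lifted into ``ambient_dim``
    by a seeded random orthogonal (norm-preserving) map and perturbed by
    isotropic Gaussian noise.  Vocabulary is ``w00000, w00001, ...`` with
    rank equal to generation order, emulating a frequency-sorted release.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.manifold == "swiss_roll":
        base, latent = _swiss_roll(rng, spec.n_words)
    elif spec.manifold == "s_curve":
        base, latent = _s_curve(rng, spec.n_words)
    else:
        latent = rng.uniform(-1.0, 1.0, (spec.n_words, spec.latent_dim))
        base = latent
    Q, _ = np.linalg.qr(rng.standard_normal((spec.ambient_dim, base.shape[1])))
    X = base @ Q.T
    if spec.noise_sigma > 0:
        X = X + rng.normal(0.0, spec.noise_sigma, X.shape)
    vocab = [f"w{i:05d}" for i in range(spec.n_words)]
    return WordEmbeddingSet(vocab=vocab, vectors=X), latent


def generate_similarity_gold(
    latent: np.ndarray,
    n_pairs: int,
    seed: int,
    vocab: list[str] | None = None,
    max_rating: float = 10.0,
    n_bins: int = 10,
) -> SimilarityDataset:
    """Gold ratings monotone in latent proximity.

    Draws ``n_pairs`` distinct unordered word pairs *stratified across the
    latent distance range* — human similarity benchmarks are constructed to
    span their rating scale from synonymous to unrelated, and uniform random
    pairs of a large vocabulary would instead be almost all unrelated, with
    near-tied ratings that carry no rank information.  Each pair is rated
    ``max_rating * exp(-dist / tau)`` with tau the median sampled latent
    distance: bounded, and strictly decreasing in latent (geodesic)
    distance.
    """
    latent = np.asarray(latent, dtype=np.float64)
    n = latent.shape[0]
    n_all = n * (n - 1) // 2
    if n_pairs > n_all:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from {n} points")
    if vocab is None:
        vocab = [f"w{i:05d}" for i in range(n)]
    rng = np.random.default_rng(seed)

    # candidate pool of distinct unordered pairs
    if n_all <= 50 * max(n_pairs, 1000):
        iu = np.triu_indices(n, k=1)
        cand = np.column_stack(iu)
    else:
        ii = rng.integers(0, n, 40 * n_pairs)
        jj = rng.integers(0, n, 40 * n_pairs)
        keep = ii < jj
        cand = np.unique(np.column_stack([ii[keep], jj[keep]]), axis=0)
    dists = np.linalg.norm(latent[cand[:, 0]] - latent[cand[:, 1]], axis=1)

    # even allocation over distance bins, topped up uniformly if bins run dry
    dmax = float(dists.max())
    if dmax <= 0:
        chosen = rng.choice(len(cand), n_pairs, replace=False)
    else:
        edges = np.linspace(0.0, dmax, n_bins + 1)
        which = np.minimum(np.digitize(dists, edges) - 1, n_bins - 1)
        per = max(1, n_pairs // n_bins)
        chosen_list = []
        for b in range(n_bins):
            pool = np.flatnonzero(which == b)
            if len(pool):
                chosen_list.append(rng.choice(pool, min(per, len(pool)), replace=False))
        chosen = np.concatenate(chosen_list) if chosen_list else np.array([], dtype=int)
        if len(chosen) > n_pairs:
            chosen = chosen[rng.choice(len(chosen), n_pairs, replace=False)]
        elif len(chosen) < n_pairs:
            rest = np.setdiff1d(np.arange(len(cand)), chosen)
            extra = rng.choice(rest, n_pairs - len(chosen), replace=False)
            chosen = np.concatenate([chosen, extra])

    dd = dists[chosen]
    tau = float(np.median(dd))
    if tau <= 0:
        tau = 1.0
    ratings = max_rating * np.exp(-dd / tau)
    pairs = [
        (vocab[cand[c, 0]], vocab[cand[c, 1]], float(r))
        for c, r in zip(chosen, ratings)
    ]
    return SimilarityDataset(pairs=pairs, name="synthetic-gold", scale=(0.0, max_rating))


def generate_zipf_frequencies(
    n_words: int,
    exponent: float = 1.05,
    seed: int | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Zipfian counts: count(rank) ~ (rank+1)^(-exponent), non-increasing.

    ``scale`` defaults to ``100 * n_words**exponent`` so the rarest word
    still gets a count of about 100, keeping integerization monotone.  The
    ``seed`` argument is accepted for interface symmetry; the counts are a
    deterministic function of (n_words, exponent, scale).
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    if scale is None:
        scale = 100.0 * float(n_words) ** exponent
    ranks = np.arange(1, n_words + 1, dtype=np.float64)
    counts = np.floor(scale * ranks**-exponent).astype(np.int64)
    return counts
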