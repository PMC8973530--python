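"""Modified Locally Linear Embedding, from scratch.

Each training point x_i is described by how its k neighbors reconstruct it.
Classical LLE keeps one reconstruction weight vector per point; when the
local Gram matrix G_i = C_i C_i^T (C_i = neighbors minus x_i) is rank
deficient, that single vector is ill-determined and the embedding unstable.
MLLE instead uses s_i linearly independent weight vectors per point,

    w_i^(l) = (1 - alpha_i) w_i(gamma) + V_i H_i(:, l),    l = 1..s_i,

where w_i(gamma) is the regularized single solution of
(G_i + gamma I) w = 1 (normalized to sum 1), V_i spans the s_i smallest
singular directions of G_i, alpha_i = ||V_i^T 1|| / sqrt(s_i) and H_i is the
Householder reflection taking v_i = V_i^T 1 to alpha_i * 1 — which makes
every column sum to one.  The embedding Y minimizes

    E(Y) = sum_i sum_l || y_i - sum_{j in J_i} w_{j,i}^l y_j ||^2

i.e. the bottom non-constant eigenvectors of the alignment matrix
Phi = sum_{i,l} (e_i - w~_i^l)(e_i - w~_i^l)^T.

The split r_i/s_i of each local spectrum follows the published MLLE
criterion: s_i counts trailing singular values whose cumulative tail-to-head
energy ratio stays below a threshold eta, which defaults to the median of
the per-point ratios rho_i (adaptive), clamped to [1, k - d].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh

from .embeddings import TrainingWindow
from .neighbors import NeighborGraph, build_neighbor_graph

logger = logging.getLogger("wordmanifold")

__all__ = [
    "LocalWeights",
    "ManifoldModel",
    "local_gram",
    "split_rank",
    "median_eta",
    "regularized_weights",
    "householder_weights",
    "alignment_matrix",
    "embed",
    "fit",
    "embedding_cost",
]


@dataclass
class LocalWeights:
    """Per-point MLLE state: neighborhood, spectrum and weight vectors."""

    J: np.ndarray           # (k,) neighbor indices
    singvals: np.ndarray    # (k,) singular values of C_i, descending
    r: int                  # leading ("large") singular values
    s: int                  # trailing => number of weight vectors, k = r + s
    w_reg: np.ndarray       # (k,) regularized single weight vector, sums to 1
    V: np.ndarray           # (k, s) smallest singular directions of G_i
    alpha: float            # ||V^T 1|| / sqrt(s)
    h: np.ndarray           # (s,) Householder unit vector (zero if degenerate)
    W: np.ndarray           # (k, s) weight columns, each sums to 1
    G: np.ndarray | None = None  # (k, k) local Gram matrix, kept on request

    @property
    def v(self) -> np.ndarray:
        return self.V.T @ np.ones(self.V.shape[0])

    @property
    def H(self) -> np.ndarray:
        return np.eye(self.s) - 2.0 * np.outer(self.h, self.h)


@dataclass
class ManifoldModel:
    """A fitted manifold re-embedding model.

    Retains everything the out-of-sample transform needs: the training
    window coordinates, the embedded coordinates, and the fit parameters.
    """

    X_train: np.ndarray          # (n, D)
    Y_train: np.ndarray          # (n, d)
    eigvals: np.ndarray          # d+1 smallest eigenvalues of Phi (ascending)
    k: int
    d: int
    metric: str
    gamma_scale: float
    eta: float | str
    eta_value: float             # the threshold actually applied
    window_start: int = 0
    window_indices: np.ndarray | None = None
    vocab: list[str] | None = None           # window words, in training order
    weights: list[LocalWeights] | None = None
    graph: NeighborGraph | None = None
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X_train.shape[0]

    @property
    def dim(self) -> int:
        return self.X_train.shape[1]

    def save(self, path) -> None:
        from ._archive import save_model

        save_model(self, path)

    @classmethod
    def load(cls, path) -> "ManifoldModel":
        from ._archive import load_model

        return load_model(cls, path)


def local_gram(X_train: np.ndarray, i: int, J_i: np.ndarray):
    """Local Gram matrix and singular spectrum of point i's neighborhood.

    Returns ``(G_i, singvals)`` where ``G_i = C C^T`` for the centered
    neighbor matrix ``C = X[J_i] - X[i]`` (k x D) and ``singvals`` are the k
    singular values of C in descending order (zero-padded when D < k).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    J_i = np.asarray(J_i, dtype=np.intp)
    k = len(J_i)
    if k < 2:
        raise ValueError("neighborhood must contain at least 2 points")
    C = X_train[J_i] - X_train[i]
    sv = np.linalg.svd(C, compute_uv=False)
    singvals = np.zeros(k)
    singvals[: len(sv)] = sv
    return C @ C.T, singvals


def split_rank(singvals: np.ndarray, k_i: int, d: int, eta: float):
    """Split the local spectrum into r_i leading and s_i trailing values.

    s_i is the number of trailing positions whose cumulative tail-to-head
    energy ratio (sum of trailing squared singular values over sum of the
    leading ones) lies below ``eta``; clamped to ``[1, max(1, k_i - d)]``.
    """
    singvals = np.asarray(singvals, dtype=np.float64)
    if len(singvals) != k_i:
        raise ValueError("singvals must have length k_i")
    evals = singvals**2
    total = evals.sum()
    s_max = max(1, k_i - d)
    if total <= 0:
        return k_i - s_max, s_max  # fully degenerate neighborhood
    csum = np.cumsum(evals)
    eta_range = total / csum[:-1] - 1.0  # tail/head ratio after each prefix
    s = int(np.searchsorted(eta_range[::-1], eta))
    s = int(np.clip(s, 1, s_max))
    return k_i - s, s


def median_eta(evals: np.ndarray, d: int) -> float:
    """Adaptive threshold: median over points of rho_i = tail(d)/head(d).

    ``evals`` is the (n, k) matrix of squared singular values, descending
    per row.
    """
    evals = np.asarray(evals, dtype=np.float64)
    head = evals[:, :d].sum(axis=1)
    tail = evals[:, d:].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(head > 0, tail / np.maximum(head, 1e-300), np.inf)
    return float(np.median(rho))


def regularized_weights(G_i: np.ndarray, gamma_scale: float = 1e-3) -> np.ndarray:
    """Single LLE weight vector: solve (G + gamma I) w = 1, normalize to sum 1.

    gamma = gamma_scale * trace(G) conditions the rank-deficient case while
    vanishing relative to the data scale; if trace(G) is zero (all neighbors
    coincide with the point) gamma = gamma_scale and the solution is uniform.
    """
    G_i = np.asarray(G_i, dtype=np.float64)
    k = G_i.shape[0]
    tr = float(np.trace(G_i))
    gamma = gamma_scale * tr if tr > 0 else gamma_scale
    w = np.linalg.solve(G_i + gamma * np.eye(k), np.ones(k))
    return w / w.sum()


@dataclass
class HouseholderWeights:
    """Output of the multi-weight construction for one point."""

    W: np.ndarray       # (k, s) columns w_i^(l), each sums to 1
    alpha: float
    v: np.ndarray       # (s,) = V^T 1
    h: np.ndarray       # (s,) Householder unit vector (zero if degenerate)

    @property
    def H(self) -> np.ndarray:
        s = len(self.h)
        return np.eye(s) - 2.0 * np.outer(self.h, self.h)


def householder_weights(
    w_reg: np.ndarray, V_i: np.ndarray, modified_tol: float = 1e-12
) -> HouseholderWeights:
    """The s_i linearly independent weight vectors of one point.

    ``V_i`` holds s_i orthonormal columns spanning the smallest singular
    directions of G_i.  The Householder reflection H mapping v = V^T 1 to
    alpha * 1 (alpha = ||v||/sqrt(s)) rotates those columns so that each
    final column (1 - alpha) w_reg + V H(:, l) sums to one.  When v is
    already proportional to 1 (or zero), H is the identity.
    """
    w_reg = np.asarray(w_reg, dtype=np.float64)
    V_i = np.asarray(V_i, dtype=np.float64)
    k, s = V_i.shape
    if s < 1:
        raise ValueError("need at least one weight vector (s >= 1)")
    v = V_i.T @ np.ones(k)
    alpha = float(np.linalg.norm(v) / np.sqrt(s))
    h = alpha * np.ones(s) - v
    norm_h = np.linalg.norm(h)
    if norm_h < modified_tol:
        h = np.zeros(s)
    else:
        h = h / norm_h
    # V @ H without forming H: reflect the columns of V across h
    VH = V_i - 2.0 * np.outer(V_i @ h, h)
    W = (1.0 - alpha) * w_reg[:, None] + VH
    return HouseholderWeights(W=W, alpha=alpha, v=v, h=h)


def alignment_matrix(weights: list[LocalWeights], n: int) -> np.ndarray:
    """Phi = sum_i sum_l (e_i - w~_i^l)(e_i - w~_i^l)^T, dense symmetric PSD.

    Because every weight column sums to one, Phi annihilates the constant
    vector (Phi 1 = 0).  Dense storage is deliberate: training windows are
    a few thousand points at most.
    """
    if len(weights) != n:
        raise ValueError(f"need weights for all {n} points, got {len(weights)}")
    Phi = np.zeros((n, n))
    for i, lw in enumerate(weights):
        if lw is None:
            raise ValueError(f"missing weights for point {i}")
        idx = np.append(lw.J, i)
        A = np.vstack([-lw.W, np.ones((1, lw.s))])  # (k+1, s)
        Phi[np.ix_(idx, idx)] += A @ A.T
    return Phi


def embed(Phi: np.ndarray, d: int, seed: int | None = None, dense_limit: int = 2000):
    """Bottom non-constant eigenvectors of the alignment matrix.

    Returns ``(Y, eigvals)`` where Y holds eigenvectors 2..d+1 (ascending
    eigenvalues; the near-zero constant eigenvector is discarded) and
    ``eigvals`` the d+1 smallest eigenvalues.  Sign convention: each
    column's largest-magnitude entry is positive, making the embedding
    deterministic.  Dense solver up to ``dense_limit`` points, shift-invert
    Lanczos beyond.
    """
    Phi = np.asarray(Phi, dtype=np.float64)
    n = Phi.shape[0]
    if d > n - 2:
        raise ValueError(f"embedding dimension d={d} needs n >= d + 2, got n={n}")
    if n <= dense_limit:
        vals, vecs = eigh(Phi, subset_by_index=[0, d])
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        try:
            vals, vecs = eigsh(Phi, k=d + 1, sigma=0.0, which="LM", v0=v0)
        except Exception:  # pragma: no cover - solver fallback
            logger.warning("sparse eigensolver failed; falling back to dense")
            vals, vecs = eigh(Phi, subset_by_index=[0, d])
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    Y = vecs[:, 1 : d + 1].copy()
    for j in range(Y.shape[1]):
        jmax = int(np.argmax(np.abs(Y[:, j])))
        if Y[jmax, j] < 0:
            Y[:, j] = -Y[:, j]
    return Y, vals[: d + 1]


def embedding_cost(Y: np.ndarray, weights: list[LocalWeights]) -> float:
    """Brute-force E(Y): the reconstruction cost summed term by term.

    Independent of the alignment-matrix route; used to validate it.
    """
    Y = np.asarray(Y, dtype=np.float64)
    total = 0.0
    for i, lw in enumerate(weights):
        for l in range(lw.s):
            resid = Y[i] - lw.W[:, l] @ Y[lw.J]
            total += float(resid @ resid)
    return total


def fit(
    window: TrainingWindow | np.ndarray,
    k: int = 500,
    d: int | None = None,
    *,
    metric: str = "normalized_geodesic",
    k_graph: int | None = None,
    gamma_scale: float = 1e-3,
    eta: float | str = "median",
    modified_tol: float = 1e-12,
    seed: int | None = None,
    keep_gram: bool = False,
    keep_graph: bool = True,
) -> ManifoldModel:
    """Fit the manifold re-embedding model on a training window.

    Pipeline: neighbor selection (normalized geodesic metric by default)
    -> per-point local spectra and multi-weight construction -> alignment
    matrix -> eigen-embedding.  ``d`` defaults to the input dimension D (the
    re-embedding transforms between two equally-dimensional coordinate
    systems); pass a smaller ``d`` for genuine dimensionality reduction.

    ``eta="median"`` uses the adaptive split threshold; a float applies a
    fixed one.  ``k <= d`` is allowed (each point then contributes a single
    weight vector) and is logged.
    """
    if isinstance(window, TrainingWindow):
        X = np.asarray(window.X_train, dtype=np.float64)
        vocab = window.vocab
        window_start = window.start
        window_indices = np.asarray(window.indices)
    else:
        X = np.asarray(window, dtype=np.float64)
        vocab = None
        window_start = 0
        window_indices = None
    n, D = X.shape
    if d is None:
        d = D
    if n <= k:
        raise ValueError(f"window of {n} points cannot support k={k} neighbors")
    if d > n - 2:
        raise ValueError(
            f"embedding dimension d={d} requires a window of at least d+2={d + 2} points"
        )
    if k <= d:
        logger.warning(
            "k=%d <= d=%d: each point contributes a single weight vector "
            "(the construction degenerates towards regularized LLE)", k, d,
        )

    graph = build_neighbor_graph(X, k=k, k_graph=k_graph, metric=metric)
    J = graph.neighborhoods

    # local spectra
    svals = np.empty((n, k))
    Vfull = np.empty((n, k, k))
    grams = []
    for i in range(n):
        C = X[J[i]] - X[i]
        U, sv, _ = np.linalg.svd(C, full_matrices=True)
        svals[i, : len(sv)] = sv
        svals[i, len(sv):] = 0.0
        Vfull[i] = U
        grams.append(C @ C.T if keep_gram else None)

    evals = svals**2
    eta_value = median_eta(evals, d) if eta == "median" else float(eta)

    weights: list[LocalWeights] = []
    for i in range(n):
        G = grams[i] if keep_gram else None
        if G is None:
            C = X[J[i]] - X[i]
            G_i = C @ C.T
        else:
            G_i = G
        w_reg = regularized_weights(G_i, gamma_scale)
        r_i, s_i = split_rank(svals[i], k, d, eta_value)
        V_i = Vfull[i][:, k - s_i :]
        hw = householder_weights(w_reg, V_i, modified_tol)
        weights.append(
            LocalWeights(
                J=J[i].copy(), singvals=svals[i].copy(), r=r_i, s=s_i,
                w_reg=w_reg, V=V_i.copy(), alpha=hw.alpha, h=hw.h, W=hw.W,
                G=G,
            )
        )

    Phi = alignment_matrix(weights, n)
    Y, eigvals = embed(Phi, d, seed=seed)

    return ManifoldModel(
        X_train=X, Y_train=Y, eigvals=eigvals, k=k, d=d, metric=metric,
        gamma_scale=gamma_scale, eta=eta, eta_value=eta_value,
        window_start=window_start, window_indices=window_indices,
        vocab=vocab, weights=weights, graph=graph if keep_graph else None,
        params={
            "k": k, "d": d, "metric": metric, "k_graph": graph.k_graph,
            "gamma_scale": gamma_scale, "eta": eta, "eta_value": eta_value,
            "modified_tol": modified_tol, "seed": seed,
        },
    )
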