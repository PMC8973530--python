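"""Neighborhood graphs and the normalized geodesic metric.

Neighbor selection happens in two stages.  A symmetrized k-nearest-neighbor
graph with Euclidean edge weights approximates the data manifold; shortest
paths on it give geodesic distances f(x_i, x_j) (Isomap-style).  These are
then normalized by the geometric mean of the two points' average geodesic
distances,

    d_ij = f(x_i, x_j) / sqrt(d(x_i) * d(x_j)),

which makes neighborhoods scale-free: a point sitting in a dense region is
not starved of neighbors by a point in a sparse one.  The final neighbor sets
J_i used by the manifold learner are the k smallest d_ij per point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import csgraph_from_dense, shortest_path
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger("wordmanifold")

__all__ = [
    "NeighborGraph",
    "pairwise_euclidean",
    "build_knn_graph",
    "geodesic_distances",
    "mean_geodesic",
    "normalized_distance",
    "final_neighborhoods",
    "euclidean_neighborhoods",
    "build_neighbor_graph",
]


@dataclass
class NeighborGraph:
    """Everything the two-stage neighbor selection produces.

    ``neighborhoods[i]`` is J_i: the k points closest to i under the
    normalized geodesic metric (or plain Euclidean in euclidean mode),
    self excluded, ordered by increasing distance with ties broken by
    smaller index.
    """

    n: int
    k: int
    k_graph: int
    metric: str
    euclid: np.ndarray  # (n, n) Euclidean distances
    graph: csr_matrix | None  # symmetrized kNN graph (None in euclidean mode)
    geodesic: np.ndarray | None  # (n, n) shortest-path distances
    mean_geo: np.ndarray | None  # (n,) mean geodesic distance per point
    normalized: np.ndarray | None  # (n, n) d_ij
    neighborhoods: np.ndarray  # (n, k) final neighbor indices


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return squareform(pdist(X))


def build_knn_graph(X: np.ndarray, k_graph: int):
    """Symmetrized k-NN graph with Euclidean edge weights.

    An edge i-j exists iff j is among i's ``k_graph`` nearest neighbors or
    vice versa.  Duplicate points yield legitimate zero-weight edges, which
    the CSR graph keeps as stored zeros (non-edges are non-stored).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k_graph < n:
        raise ValueError(f"need 1 <= k_graph < n, got k_graph={k_graph}, n={n}")
    dist = pairwise_euclidean(X)
    dd = dist.copy()
    np.fill_diagonal(dd, np.inf)
    nn = np.argsort(dd, axis=1, kind="stable")[:, :k_graph]
    dense = np.full((n, n), np.inf)
    rows = np.repeat(np.arange(n), k_graph)
    dense[rows, nn.ravel()] = dist[rows, nn.ravel()]
    dense = np.minimum(dense, dense.T)  # symmetrize (union of edge sets)
    np.fill_diagonal(dense, np.inf)
    return csgraph_from_dense(dense, null_value=np.inf)


def geodesic_distances(graph, X: np.ndarray | None = None) -> np.ndarray:
    """All-pairs shortest-path distances on a k-NN graph.

    Pairs split across connected components get the ambient Euclidean
    distance (requires ``X``); the substitution is logged.  Infinite
    distances would otherwise poison the mean-distance normalization.
    """
    geo = shortest_path(graph, method="D", directed=False)
    disconnected = ~np.isfinite(geo)
    if disconnected.any():
        n_pairs = int(disconnected.sum()) // 2
        if X is None:
            raise ValueError(
                f"graph has disconnected components ({n_pairs} unreachable pairs) "
                "and no ambient coordinates were given for the Euclidean fallback"
            )
        logger.warning(
            "k-NN graph is disconnected: %d pairs fall back to ambient Euclidean distance",
            n_pairs,
        )
        euc = pairwise_euclidean(X)
        geo[disconnected] = euc[disconnected]
    return geo


def mean_geodesic(geodesic: np.ndarray) -> np.ndarray:
    """d(x_i): mean geodesic distance of i to the other n-1 points."""
    n = geodesic.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    return geodesic.sum(axis=1) / (n - 1)  # diagonal is zero


def normalized_distance(
    geodesic: np.ndarray, mean_geo: np.ndarray | None = None
) -> np.ndarray:
    """d_ij = f(x_i,x_j) / sqrt(d(x_i) d(x_j)); symmetric, zero diagonal.

    Invariant to uniform rescaling of the input coordinates, since both the
    geodesics and the per-point means scale linearly.
    """
    if mean_geo is None:
        mean_geo = mean_geodesic(geodesic)
    mean_geo = np.asarray(mean_geo, dtype=np.float64)
    if np.any(mean_geo <= 0):
        raise ValueError(
            "mean geodesic distance is zero for some point: all points coincide "
            "(degenerate input)"
        )
    return geodesic / np.sqrt(np.outer(mean_geo, mean_geo))


def _knn_from_dense(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    dd = dist.copy()
    np.fill_diagonal(dd, np.inf)
    # stable argsort breaks distance ties by smaller index
    return np.argsort(dd, axis=1, kind="stable")[:, :k]


def final_neighborhoods(normalized: np.ndarray, k: int) -> np.ndarray:
    """J_i: indices of the k smallest normalized distances per point."""
    return _knn_from_dense(normalized, k)


def euclidean_neighborhoods(X: np.ndarray, k: int) -> np.ndarray:
    """Plain Euclidean k-NN (self excluded), the classical LLE choice."""
    return _knn_from_dense(pairwise_euclidean(X), k)


def build_neighbor_graph(
    X: np.ndarray,
    k: int,
    k_graph: int | None = None,
    metric: str = "normalized_geodesic",
) -> NeighborGraph:
    """Run the full neighbor-selection pipeline over the training window.

    ``metric="normalized_geodesic"`` (default) performs the two-stage
    selection; ``metric="euclidean"`` skips the graph machinery and uses
    direct Euclidean k-NN (used for parity checks against classical MLLE).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if metric not in ("normalized_geodesic", "euclidean"):
        raise ValueError(f"unknown neighbor metric {metric!r}")
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    k_graph = k if k_graph is None else k_graph
    euclid = pairwise_euclidean(X)
    if metric == "euclidean":
        return NeighborGraph(
            n=n, k=k, k_graph=k_graph, metric=metric, euclid=euclid,
            graph=None, geodesic=None, mean_geo=None, normalized=None,
            neighborhoods=_knn_from_dense(euclid, k),
        )
    graph = build_knn_graph(X, k_graph)
    geo = geodesic_distances(graph, X)
    mg = mean_geodesic(geo)
    norm = normalized_distance(geo, mg)
    return NeighborGraph(
        n=n, k=k, k_graph=k_graph, metric=metric, euclid=euclid,
        graph=graph, geodesic=geo, mean_geo=mg, normalized=norm,
        neighborhoods=final_neighborhoods(norm, k),
    )
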