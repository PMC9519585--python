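"""Neighbourhood graphs over connectivity fingerprints.

Five variants feed the spectral embedding: unweighted/weighted k-nearest-
neighbour graphs, unweighted/weighted radius graphs, and a fully-connected
weighted graph.  Neighbourhoods are defined on the squared Euclidean
distance between samples; weights are Pearson correlations rescaled to
[0, 1] (0 = perfect negative correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "NeighborhoodGraph",
    "DisconnectedGraphError",
    "correlation_weight_matrix",
    "knn_graph",
    "radius_graph",
    "full_graph",
    "build_graph",
    "GRAPH_VARIANTS",
]

GRAPH_VARIANTS = (
    "knn_unweighted",
    "knn_weighted",
    "radius_unweighted",
    "radius_weighted",
    "full_weighted",
)


class DisconnectedGraphError(ValueError):
    """The neighbourhood graph is not connected; the trial is invalid."""


@dataclass
class NeighborhoodGraph:
    """Symmetric non-negative affinity matrix with zero diagonal."""

    affinity: np.ndarray
    variant: str
    weighted: bool
    params: dict

    def __post_init__(self) -> None:
        a = np.asarray(self.affinity, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity must be square")
        self.affinity = a

    @property
    def n_nodes(self) -> int:
        return self.affinity.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = csgraph.connected_components(self.affinity > 0, directed=False)
        return n_comp == 1


def correlation_weight_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of rows, rescaled to [0, 1]: w=(r+1)/2."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"row {int(np.argmin(sd))} has zero variance")
    r = np.corrcoef(X)
    r = (r + r.T) / 2.0  # corrcoef is symmetric only up to float noise
    return np.clip((r + 1.0) / 2.0, 0.0, 1.0)


def _sq_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, dtype=float), metric="sqeuclidean"))


def _apply_weights(adj: np.ndarray, X: np.ndarray, weighted: bool) -> np.ndarray:
    if not weighted:
        return adj.astype(float)
    return adj * correlation_weight_matrix(X)


def knn_graph(X: np.ndarray, k: int, weighted: bool = False) -> NeighborhoodGraph:
    """k-nearest-neighbour graph on squared Euclidean distance.

    The directed kNN relation is symmetrized by OR: an edge exists if either
    sample is within the k nearest neighbours of the other.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    d2 = _sq_distances(X)
    np.fill_diagonal(d2, np.inf)  # a sample is not its own neighbour
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, order.ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    graph = _apply_weights(adj, X, weighted)
    variant = "knn_weighted" if weighted else "knn_unweighted"
    return NeighborhoodGraph(graph, variant, weighted, {"k": int(k)})


def radius_graph(
    X: np.ndarray, eps_radius: float, weighted: bool = False
) -> NeighborhoodGraph:
    """Radius graph: edge iff squared Euclidean distance <= eps_radius."""
    if eps_radius <= 0:
        raise ValueError("eps_radius must be > 0")
    X = np.asarray(X, dtype=float)
    adj = _sq_distances(X) <= eps_radius
    np.fill_diagonal(adj, False)
    graph = _apply_weights(adj, X, weighted)
    variant = "radius_weighted" if weighted else "radius_unweighted"
    return NeighborhoodGraph(graph, variant, weighted, {"eps_radius": float(eps_radius)})


def full_graph(X: np.ndarray) -> NeighborhoodGraph:
    """Fully connected weighted graph: every off-diagonal pair gets its weight."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    w = correlation_weight_matrix(X)
    np.fill_diagonal(w, 0.0)
    return NeighborhoodGraph(w, "full_weighted", True, {})


def build_graph(X: np.ndarray, variant: str, **params) -> NeighborhoodGraph:
    """Dispatch on one of the five spectral-embedding graph variants."""
    if variant == "knn_unweighted":
        return knn_graph(X, params["k"], weighted=False)
    if variant == "knn_weighted":
        return knn_graph(X, params["k"], weighted=True)
    if variant == "radius_unweighted":
        return radius_graph(X, params["eps_radius"], weighted=False)
    if variant == "radius_weighted":
        return radius_graph(X, params["eps_radius"], weighted=True)
    if variant == "full_weighted":
        return full_graph(X)
    raise ValueError(f"unknown graph variant: {variant!r}")
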