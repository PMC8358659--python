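"""Similarity graphs and graph Laplacians for the locality-preserving term.

The source domain gets a directed k-nearest-neighbour graph with Gaussian
weights, symmetrized by elementwise maximum; the label-scarce target domain
gets a binary same-class graph. The combinatorial Laplacian L = Deg - Sim
turns either graph into the quadratic form

    x L x^T = 1/2 * sum_ij G_ij (x_i - x_j)^2,

which is what the locality criterion penalizes for each projected
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .domain import LabeledDomain
from .errors import InputError

__all__ = [
    "SimilarityGraph",
    "GraphLaplacian",
    "knn_source_graph",
    "target_label_graph",
    "laplacian",
]

AUTO = "auto"


@dataclass
class SimilarityGraph:
    """Symmetric nonnegative n x n similarity weights in [0, 1]."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InputError(f"similarity matrix must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise InputError("similarity matrix contains non-finite values")
        if np.any(W < 0) or np.any(W > 1):
            raise InputError("similarity weights must lie in [0, 1]")
        if not np.allclose(W, W.T, atol=1e-12):
            raise InputError("similarity matrix must be symmetric")
        self.weights = W

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphLaplacian:
    """Combinatorial Laplacian L = Deg - Sim of a similarity graph."""

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def knn_source_graph(
    Y: LabeledDomain, k: int = 5, sigma: float | str = AUTO
) -> SimilarityGraph:
    """Gaussian-weighted k-NN similarity graph of a domain's samples.

    Raw entry ``G[i, j] = exp(-||y_i - y_j||^2 / sigma)`` iff sample ``i``
    is among the ``k`` nearest neighbours of sample ``j`` (self excluded;
    distance ties broken by index order), zero otherwise; the directed
    result is then symmetrized by elementwise maximum so every directed
    edge survives.

    Parameters
    ----------
    Y
        The domain whose samples (columns) are the graph nodes.
    k
        Neighbour count, ``1 <= k < n``.
    sigma
        Gaussian bandwidth dividing the *squared* distance. ``"auto"``
        uses the median of the off-diagonal pairwise squared distances
        (falling back to 1.0 if that median is zero).
    """
    n = Y.n
    if not 1 <= k < n:
        raise InputError(f"k-NN needs 1 <= k < n, got k={k}, n={n}")
    d2 = squareform(pdist(Y.X.T, metric="sqeuclidean"))
    if sigma == AUTO:
        off = d2[~np.eye(n, dtype=bool)]
        med = float(np.median(off))
        sigma = med if med > 0 else 1.0
    sigma = float(sigma)
    if sigma <= 0:
        raise InputError(f"sigma must be positive, got {sigma}")

    G = np.zeros((n, n))
    for j in range(n):
        order = np.argsort(d2[:, j], kind="stable")
        neigh = [i for i in order if i != j][:k]
        G[neigh, j] = np.exp(-d2[neigh, j] / sigma)
    G = np.maximum(G, G.T)
    np.fill_diagonal(G, 0.0)
    return SimilarityGraph(G)


def target_label_graph(labels: np.ndarray) -> SimilarityGraph:
    """Binary same-class similarity graph (diagonal kept at 1).

    The unit diagonal is harmless: self-edges contribute zero to the
    Laplacian quadratic form.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size == 0:
        raise InputError("empty label vector")
    G = (labels[:, None] == labels[None, :]).astype(float)
    return SimilarityGraph(G)


def laplacian(G: SimilarityGraph) -> GraphLaplacian:
    """Combinatorial Laplacian ``L = Deg - Sim`` of a similarity graph.

    ``Deg`` is diagonal with row sums of the weights. The result is
    symmetric, has zero row sums, and is positive semidefinite.
    """
    W = G.weights
    L = np.diag(W.sum(axis=1)) - W
    return GraphLaplacian(L)
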