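"""Space-informed clustering of single cells.

An expression-similarity KNN graph (built on principal components of the
normalized expression) carries the transcriptomic topology; its edges are
re-weighted by pseudo-space proximity so that Leiden community detection can
split transcriptomically similar but spatially separated subpopulations.

Two weighting strategies are provided:

* ``"gaussian"`` — w_ij = exp(-d_ij^2 / (2 l^2)) with d_ij the Euclidean
  pseudo-space distance and l a characteristic length scale (how fast the
  spatial affinity decays with distance);
* ``"graph"`` — w_ij = 1/(alpha + d_ij) + beta with d_ij the hop distance
  on a KNN graph built in pseudo-space (1 for neighbors, 2 for neighbors of
  neighbors, ...), capped at ``max_hop``; alpha and beta are pseudocounts
  guarding against excessively large and small weights.

Pseudo-space distances are taken in the reference coordinate frame, so l is
expressed in the reference's spatial units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SpaceWeightConfig",
    "SpaceWeightedGraph",
    "ClusterResult",
    "build_expression_graph",
    "gaussian_weight",
    "graph_hop_weight",
    "compute_space_weights",
    "space_informed_leiden",
]


@dataclass
class SpaceWeightConfig:
    """Parameters of graph construction and spatial edge weighting."""

    strategy: str = "gaussian"     # "gaussian" or "graph"
    l: float = 20.0                # characteristic length scale (coord units)
    alpha: float = 1.0             # hop-weight pseudocount (large-weight guard)
    beta: float = 1.0              # hop-weight pseudocount (small-weight guard)
    k_expr: int = 20               # expression KNN neighbors
    n_pcs: int = 50                # PCs for the expression graph
    k_space: int = 20              # pseudo-space KNN neighbors ("graph" mode)
    max_hop: int = 6               # hop-distance cap ("graph" mode)

    def __post_init__(self) -> None:
        if self.strategy not in ("gaussian", "graph"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass
class SpaceWeightedGraph:
    """Undirected expression graph with spatial edge weights."""

    nodes: list[str]
    edges: np.ndarray      # (n_edges, 2) int pairs, i < j
    weights: np.ndarray    # positive, one per edge

    def __post_init__(self) -> None:
        if len(self.edges) and (self.weights <= 0).any():
            raise ValueError("edge weights must be positive")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=len(self.nodes), edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(map(float, self.weights))
        return g


@dataclass
class ClusterResult:
    labels: np.ndarray
    resolution_used: float
    n_clusters: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.n_clusters = int(len(np.unique(self.labels)))


def _knn_edges(X: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized directed k-NN relations as undirected (i<j) pairs."""
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    pairs = set()
    for i in range(n):
        for j in idx[i]:
            if j == i:
                continue
            pairs.add((min(i, int(j)), max(i, int(j))))
    # self excluded above; a duplicate point may push self out of the k+1
    # neighbors, leaving k+1 foreign neighbors — harmless for a union graph
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def build_expression_graph(
    expr: ExpressionDataset | np.ndarray,
    n_pcs: int = 50,
    k_expr: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression KNN graph on principal components.

    Returns ``(edges, pcs)``: the union-symmetrized undirected edge array and
    the PC coordinates used. ``n_pcs`` is clamped to ``n_obs - 1`` /
    ``n_genes`` with a warning when the data are too small.
    """
    X = expr.matrix if isinstance(expr, ExpressionDataset) else np.asarray(expr)
    n_obs, n_genes = X.shape
    max_pcs = min(n_obs - 1, n_genes)
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d clamped to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    return _knn_edges(pcs, k_expr), pcs


def gaussian_weight(d, l: float):
    """Gaussian distance decay w = exp(-d^2 / (2 l^2)); w(0) = 1."""
    if l <= 0:
        raise ValueError("characteristic length scale l must be positive")
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d**2) / (2.0 * l**2))
    return float(out) if out.ndim == 0 else out


def graph_hop_weight(
    coords: np.ndarray,
    edges: np.ndarray,
    k_space: int = 20,
    alpha: float = 1.0,
    beta: float = 1.0,
    max_hop: int = 6,
) -> np.ndarray:
    """Hop-distance weights w = 1/(alpha + d) + beta per expression edge.

    A KNN graph is built on the pseudo-space coordinates; d is the unweighted
    shortest-path hop count between the edge's endpoints on that graph,
    capped at ``max_hop`` (unreachable pairs also get ``max_hop``).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    edges = np.asarray(edges, dtype=int)
    space_edges = _knn_edges(coords, min(k_space, n - 1))
    rows = np.concatenate([space_edges[:, 0], space_edges[:, 1]])
    cols = np.concatenate([space_edges[:, 1], space_edges[:, 0]])
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    sources = np.unique(edges[:, 0]) if len(edges) else np.array([], dtype=int)
    hop = np.full((n, n), np.inf)
    if len(sources):
        dist = dijkstra(
            adj, directed=False, unweighted=True, indices=sources,
            limit=max_hop,
        )
        hop[sources] = dist
    d = np.minimum(hop[edges[:, 0], edges[:, 1]], max_hop) if len(edges) \
        else np.array([])
    return 1.0 / (alpha + d) + beta


def compute_space_weights(
    coords: np.ndarray,
    edges: np.ndarray,
    cfg: SpaceWeightConfig | None = None,
) -> np.ndarray:
    """Spatial weight per expression edge under the configured strategy."""
    cfg = cfg or SpaceWeightConfig()
    coords = np.asarray(coords, dtype=float)
    if len(edges) == 0:
        return np.array([])
    if edges.max() >= coords.shape[0]:
        raise ValueError("pseudo-space coordinates do not cover all nodes")
    if cfg.strategy == "gaussian":
        d = np.linalg.norm(
            coords[edges[:, 0]] - coords[edges[:, 1]], axis=1
        )
        return gaussian_weight(d, cfg.l)
    return graph_hop_weight(
        coords, edges, k_space=cfg.k_space, alpha=cfg.alpha, beta=cfg.beta,
        max_hop=cfg.max_hop,
    )


def _leiden_once(
    g: ig.Graph, weights, resolution: float, seed: int
) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,  # iterate until the partition stops improving
    )
    return np.asarray(part.membership, dtype=int)


def space_informed_leiden(
    graph: SpaceWeightedGraph | ig.Graph,
    weights: np.ndarray | None = None,
    target_k: int | None = None,
    resolution: float | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Leiden partition of the space-weighted expression graph.

    Exactly one of ``target_k`` / ``resolution`` must be given. With
    ``target_k``, the resolution is found by bisection on [1e-3, 10]
    (<= 40 iterations), returning the partition whose cluster count is
    closest to ``target_k`` (ties toward fewer clusters). Deterministic for
    a fixed seed.
    """
    if (target_k is None) == (resolution is None):
        raise ValueError("give exactly one of target_k or resolution")
    if isinstance(graph, SpaceWeightedGraph):
        g = graph.to_igraph()
        w = g.es["weight"]
    else:
        g = graph
        w = None if weights is None else list(map(float, weights))
    n = g.vcount()
    if target_k is not None and target_k > n:
        raise ValueError(f"target_k={target_k} exceeds {n} cells")

    if resolution is not None:
        labels = _leiden_once(g, w, resolution, seed)
        return ClusterResult(labels, resolution, len(np.unique(labels)), seed)

    lo, hi = 1e-3, 10.0
    best: tuple[int, int, float, np.ndarray] | None = None

    def consider(res: float) -> int:
        nonlocal best
        labels = _leiden_once(g, w, res, seed)
        k = len(np.unique(labels))
        cand = (abs(k - target_k), k, res, labels)
        if best is None or cand[:2] < best[:2]:
            best = cand
        return k

    consider(lo)
    consider(hi)
    for _ in range(40):
        if best is not None and best[0] == 0:
            break
        mid = 0.5 * (lo + hi)
        k = consider(mid)
        if k < target_k:
            lo = mid
        else:
            hi = mid
    assert best is not None
    if best[0] > 2:
        logger.warning(
            "bisection reached %d clusters for target_k=%d", best[1], target_k
        )
    return ClusterResult(best[3], best[2], best[1], seed)
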