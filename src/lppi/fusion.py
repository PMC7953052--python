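"""Attribute-similarity graph construction and topology/attribute fusion.

A protein's attribute vector (e.g. binary gene-set memberships) induces a
second graph on the same node set whose edge weights are cosine similarities.
The fused adjacency is the weighted sum

    A_fusion = A_topo + beta * A_feat

so a single non-negative scalar ``beta`` controls how much attribute
similarity contributes relative to observed interactions. Computing all-pairs
similarity is quadratic in the node count, so the similarity graph is
sparsified to a symmetrized k-nearest-neighbour graph; an exact dense mode is
kept for small graphs and serves as the oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, ShapeError
from .graph import AttributeMatrix, Graph

__all__ = [
    "FusionConfig",
    "cosine_similarity",
    "build_feature_graph",
    "fuse",
]

# above this node count the kNN search goes through sklearn ball-tree/brute
# instead of materialising the full similarity matrix
_DENSE_LIMIT = 2000


@dataclass
class FusionConfig:
    """Fusion weight ``beta`` (>= 0) and kNN sparsification degree ``knn_k``."""

    beta: float = 0.1
    knn_k: int = 10

    def __post_init__(self):
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.knn_k < 1:
            raise ParameterError("knn_k must be >= 1")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity <a,b>/(|a||b|); 0 if either vector is all-zero."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"vector lengths differ: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    out = np.zeros_like(x, dtype=np.float64)
    nz = norms > 0
    out[nz] = x[nz] / norms[nz, None]
    return out


def build_feature_graph(attrs: AttributeMatrix, knn_k: int = 10) -> Graph:
    """Symmetrized kNN cosine-similarity graph over the attribute rows.

    Each node is linked to its ``knn_k`` most similar other nodes (weight =
    cosine similarity); the union of directed selections is kept, candidate
    edges with zero similarity are dropped, and all-zero attribute rows
    contribute no edges. Ties in the kNN ranking are broken by ascending
    node id so the result is deterministic.
    """
    n = attrs.n_nodes
    if knn_k >= n:
        raise ParameterError(f"knn_k={knn_k} must be < n_nodes={n}")
    xn = _normalize_rows(attrs.values)

    rows, cols, vals = [], [], []
    if n <= _DENSE_LIMIT:
        sim = xn @ xn.T
        np.fill_diagonal(sim, -np.inf)
        # stable sort on (-similarity, node id): lexsort's last key dominates
        for u in range(n):
            order = np.lexsort((np.arange(n), -sim[u]))[:knn_k]
            for v in order:
                w = sim[u, v]
                if w > 0:
                    rows.append(u)
                    cols.append(int(v))
                    vals.append(float(w))
    else:
        nn = NearestNeighbors(n_neighbors=knn_k + 1, metric="cosine")
        nn.fit(xn)
        dist, idx = nn.kneighbors(xn)
        for u in range(n):
            taken = 0
            for d, v in sorted(
                zip(dist[u], idx[u]), key=lambda t: (t[0], t[1])
            ):
                if v == u or taken >= knn_k:
                    continue
                w = 1.0 - d
                if w > 1e-12:
                    rows.append(u)
                    cols.append(int(v))
                    vals.append(float(w))
                taken += 1

    if not rows:
        return Graph(n)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)  # union symmetrization; weights are symmetric anyway
    return Graph(n, a)


def fuse(topo: Graph, feat: Graph, cfg: FusionConfig | None = None) -> Graph:
    """Weighted sum of topology and attribute-similarity adjacencies.

    ``w_fused(u,v) = w_topo(u,v) + beta * w_feat(u,v)``; the node set is
    unchanged, and similarity-only pairs become new (down-weighted) edges.
    """
    cfg = cfg or FusionConfig()
    if topo.n_nodes != feat.n_nodes:
        raise ShapeError(
            f"node counts differ: topo {topo.n_nodes} vs feat {feat.n_nodes}"
        )
    fused = topo.adjacency + cfg.beta * feat.adjacency
    return Graph(topo.n_nodes, fused, topo.node_names)
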