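"""Spectral graph coarsening hierarchy and Laplacian-smoothing refinement.

Coarsening replaces eigenvector computation with a cheap spectral sketch:
a handful of random vectors are low-pass filtered by Gauss-Seidel sweeps on
the graph Laplacian, leaving each node a short signature row. Nodes joined by
an edge whose signature rows are nearly parallel (high squared-cosine
"spectral affinity") are merged pairwise; the coarse adjacency is the Galerkin
product H^T A H of the fine adjacency with the one-hot assignment matrix H,
which conserves total edge weight. Repeating this l times yields a hierarchy
of graphs whose coarsest member is cheap to embed.

Refinement runs the hierarchy backwards: a coarse embedding is prolonged to
the finer level through H and then smoothed k times with the sigma-self-looped
symmetric-normalized adjacency

    S = D~^{-1/2} (A + sigma I) D~^{-1/2},   D~ = D + sigma I,

whose spectrum lies in [-1, 1], so smoothing never amplifies the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError, ShapeError
from .graph import Graph

__all__ = [
    "TestVectors",
    "MappingOperator",
    "Hierarchy",
    "RefineConfig",
    "smooth_test_vectors",
    "spectral_affinity",
    "coarsen_once",
    "build_hierarchy",
    "refine_level",
    "refine_all",
]

# a coarsening pass that shrinks the node count by less than this fraction
# stops the hierarchy (prevents looping on graphs that no longer contract)
_MIN_SHRINK = 0.02


@dataclass
class TestVectors:
    """N x t matrix of Gauss-Seidel-smoothed random vectors.

    Row p is node p's spectral signature; t is the vector count.
    """

    values: np.ndarray
    gs_iters: int
    seed: int

    __test__ = False  # keep pytest from collecting this as a test class

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]


@dataclass
class MappingOperator:
    """Fine -> coarse node assignment between two adjacent hierarchy levels."""

    assignment: np.ndarray  # assignment[fine_id] = coarse_id
    n_coarse: int

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.assignment.size and (
            self.assignment.min() < 0 or self.assignment.max() >= self.n_coarse
        ):
            raise ValueError("coarse ids must lie in 0..n_coarse-1")

    @property
    def n_fine(self) -> int:
        return self.assignment.shape[0]

    def matrix(self) -> sp.csr_matrix:
        """One-hot n_fine x n_coarse assignment matrix H."""
        n_f = self.n_fine
        return sp.csr_matrix(
            (np.ones(n_f), (np.arange(n_f), self.assignment)),
            shape=(n_f, self.n_coarse),
        )


@dataclass
class Hierarchy:
    """Graphs from fine (level 0) to coarse, with the mappings between them."""

    levels: list[Graph]
    mappings: list[MappingOperator] = field(default_factory=list)

    def __post_init__(self):
        if len(self.mappings) != len(self.levels) - 1:
            raise ShapeError("need exactly one mapping per adjacent level pair")

    @property
    def depth(self) -> int:
        """Number of coarsening steps actually performed."""
        return len(self.mappings)

    @property
    def coarsest(self) -> Graph:
        return self.levels[-1]


@dataclass
class RefineConfig:
    """Smoothing power k (>= 0) and self-loop weight sigma (> 0)."""

    power: int = 2
    sigma: float = 1.0

    def __post_init__(self):
        if self.power < 0:
            raise ParameterError("power must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")


# ---------------------------------------------------------------------------
# smoothing and affinity


def smooth_test_vectors(
    g: Graph, t: int = 16, gs_iters: int = 2, seed: int = 0, sigma: float = 1.0
) -> TestVectors:
    """Low-pass filter t random vectors with Gauss-Seidel sweeps on L~ x = 0.

    L~ is the Laplacian of g with sigma-weighted self-loops (which keep the
    update well defined on isolated nodes). Starting from standard-Gaussian
    vectors, each sweep updates node i in place to the sigma-damped weighted
    mean of its neighbours; after ``gs_iters`` sweeps the per-vector mean is
    removed, suppressing the constant eigenvector that would otherwise make
    every pairwise affinity approach 1.
    """
    if t < 1:
        raise ParameterError("t must be >= 1")
    if gs_iters < 1:
        raise ParameterError("gs_iters must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((g.n_nodes, t))
    a = g.adjacency
    deg = g.degrees()
    indptr, indices, data = a.indptr, a.indices, a.data
    for _ in range(gs_iters):
        for i in range(g.n_nodes):
            lo, hi = indptr[i], indptr[i + 1]
            nbr_sum = data[lo:hi] @ x[indices[lo:hi]] if hi > lo else 0.0
            x[i] = (sigma * x[i] + nbr_sum) / (deg[i] + sigma)
    x -= x.mean(axis=0, keepdims=True)
    return TestVectors(values=x, gs_iters=gs_iters, seed=seed)


def spectral_affinity(tv: TestVectors, p: int, q: int) -> float:
    """Squared cosine of nodes p and q's signature rows, in [0, 1]."""
    if p == q:
        raise ValueError("affinity is defined for distinct nodes")
    kp, kq = tv.values[p], tv.values[q]
    denom = (kp @ kp) * (kq @ kq)
    if denom == 0:
        return 0.0
    return float((kp @ kq) ** 2 / denom)


def _edge_affinities(tv: TestVectors, u: np.ndarray, v: np.ndarray):
    """Vectorized spectral affinity for the edge arrays (u, v)."""
    k = tv.values
    num = np.einsum("ij,ij->i", k[u], k[v]) ** 2
    den = np.einsum("ij,ij->i", k[u], k[u]) * np.einsum(
        "ij,ij->i", k[v], k[v]
    )
    out = np.zeros(len(u))
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


# ---------------------------------------------------------------------------
# coarsening


def coarsen_once(
    g: Graph, tv: TestVectors, seed: int = 0
) -> tuple[Graph, MappingOperator]:
    """One pass of affinity-ranked pairwise merging along graph edges.

    Edges are sorted by spectral affinity (descending, ties by endpoint ids);
    an edge merges its endpoints iff both are still unmatched, so clusters
    have at most two members per pass and the coarse node count is at least
    half the fine count. Unmatched nodes survive as singletons. The coarse
    adjacency is the Galerkin product H^T A H with its diagonal (intra-cluster
    weight) removed; the diagonal mass is what weight conservation accounts
    for in the tests.
    """
    n = g.n_nodes
    if n == 0:
        raise ValueError("cannot coarsen an empty graph")
    u, v, _ = g.edge_arrays()
    aff = _edge_affinities(tv, u, v) if len(u) else np.zeros(0)
    order = np.lexsort((v, u, -aff))

    match = np.full(n, -1, dtype=np.int64)
    for e in order:
        a, b = u[e], v[e]
        if match[a] == -1 and match[b] == -1:
            match[a] = b
            match[b] = a

    # coarse ids in order of each cluster's minimum fine id (deterministic)
    assignment = np.full(n, -1, dtype=np.int64)
    next_id = 0
    for i in range(n):
        if assignment[i] != -1:
            continue
        assignment[i] = next_id
        if match[i] > i:
            assignment[match[i]] = next_id
        next_id += 1

    h = MappingOperator(assignment, next_id)
    hm = h.matrix()
    coarse_adj = (hm.T @ g.adjacency @ hm).tocsr()
    coarse_adj.setdiag(0.0)
    coarse_adj.eliminate_zeros()
    return Graph(next_id, coarse_adj), h


def build_hierarchy(
    g: Graph,
    level: int = 1,
    t: int = 16,
    gs_iters: int = 2,
    seed: int = 0,
    sigma: float = 1.0,
) -> Hierarchy:
    """Apply smoothing + coarsening ``level`` times, re-sketching each level.

    Stops early (recording the achieved depth) when a pass shrinks the node
    count by less than 2%, so degenerate graphs cannot loop forever.
    """
    if level < 0:
        raise ParameterError("level must be >= 0")
    levels = [g]
    mappings: list[MappingOperator] = []
    current = g
    for i in range(level):
        tv = smooth_test_vectors(
            current, t=t, gs_iters=gs_iters, seed=seed + i, sigma=sigma
        )
        coarse, h = coarsen_once(current, tv, seed=seed + i)
        if coarse.n_nodes > (1 - _MIN_SHRINK) * current.n_nodes:
            break
        levels.append(coarse)
        mappings.append(h)
        current = coarse
    return Hierarchy(levels, mappings)


# ---------------------------------------------------------------------------
# refinement


def _smoothing_operator_apply(
    g: Graph, e: np.ndarray, sigma: float, power: int
) -> np.ndarray:
    """Apply (D~^{-1/2} (A + sigma I) D~^{-1/2})^power to the rows of e."""
    inv_sqrt = 1.0 / np.sqrt(g.degrees() + sigma)
    a = g.adjacency
    for _ in range(power):
        scaled = e * inv_sqrt[:, None]
        e = (a @ scaled + sigma * scaled) * inv_sqrt[:, None]
    return e


def refine_level(
    e_coarse: np.ndarray,
    h: MappingOperator,
    g_fine: Graph,
    cfg: RefineConfig | None = None,
) -> np.ndarray:
    """Prolong a coarse embedding through H and smooth it on the fine graph.

    With ``power=0`` this is a pure projection: each fine node receives its
    cluster's coarse row verbatim.
    """
    cfg = cfg or RefineConfig()
    e_coarse = np.asarray(e_coarse, dtype=np.float64)
    if e_coarse.shape[0] != h.n_coarse:
        raise ShapeError(
            f"embedding has {e_coarse.shape[0]} rows, mapping expects "
            f"{h.n_coarse}"
        )
    if h.n_fine != g_fine.n_nodes:
        raise ShapeError(
            f"mapping covers {h.n_fine} fine nodes, graph has "
            f"{g_fine.n_nodes}"
        )
    e_fine = e_coarse[h.assignment]  # H @ E_coarse for one-hot H
    return _smoothing_operator_apply(g_fine, e_fine, cfg.sigma, cfg.power)


def refine_all(
    hier: Hierarchy,
    e_coarsest: np.ndarray,
    cfg: RefineConfig | None = None,
) -> np.ndarray:
    """Refine a coarsest-level embedding back to the original graph."""
    cfg = cfg or RefineConfig()
    e = np.asarray(e_coarsest, dtype=np.float64)
    if e.shape[0] != hier.coarsest.n_nodes:
        raise ShapeError(
            f"embedding has {e.shape[0]} rows, coarsest level has "
            f"{hier.coarsest.n_nodes} nodes"
        )
    for lvl in range(hier.depth - 1, -1, -1):
        e = refine_level(e, hier.mappings[lvl], hier.levels[lvl], cfg)
    return e
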