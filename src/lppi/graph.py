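"""Undirected weighted graph container, attribute matrices, and plain-text I/O.

The graph model is deliberately small: protein interaction networks are
undirected, weights are non-negative, node identifiers are 0-based contiguous
integers, and self-loops are never stored (smoothing operators re-introduce
sigma-weighted self-loops internally where the algorithm calls for them).
String protein identifiers are mapped to integers at the I/O boundary and kept
on the graph for round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import GraphFormatError, ShapeError

__all__ = [
    "Graph",
    "AttributeMatrix",
    "EdgeListReport",
    "read_edge_list",
    "write_edge_list",
    "load_attributes",
    "read_compartments",
    "write_compartments",
    "density",
]


@dataclass
class EdgeListReport:
    """Bookkeeping from :func:`read_edge_list`.

    ``n_raw_lines`` counts edge records in the file, ``n_self_loops`` the
    removed self-interactions, ``n_duplicates`` the collapsed repeats.
    ``n_unique_directed`` / ``n_unique_undirected`` give the surviving pair
    count under the two possible readings of the input (ordered pairs that
    were symmetrized, vs. already-unordered pairs), so a user can check either
    interpretation against a dataset's published statistics.
    """

    n_raw_lines: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    n_unique_directed: int = 0
    n_unique_undirected: int = 0


class Graph:
    """Undirected weighted graph backed by a symmetric CSR adjacency.

    Invariants enforced on construction: symmetry, zero diagonal, finite
    non-negative weights.
    """

    def __init__(
        self,
        n_nodes: int,
        adjacency: sp.spmatrix | None = None,
        node_names: list[str] | None = None,
        *,
        _validate: bool = True,
    ):
        if n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        self.n_nodes = int(n_nodes)
        if adjacency is None:
            adjacency = sp.csr_matrix((n_nodes, n_nodes))
        adjacency = sp.csr_matrix(adjacency, dtype=np.float64)
        if adjacency.shape != (n_nodes, n_nodes):
            raise ShapeError(
                f"adjacency shape {adjacency.shape} != ({n_nodes}, {n_nodes})"
            )
        if _validate:
            adjacency = adjacency.copy()
            adjacency.setdiag(0.0)
            adjacency.eliminate_zeros()
            if adjacency.nnz:
                if not np.all(np.isfinite(adjacency.data)):
                    raise ValueError("edge weights must be finite")
                if adjacency.data.min() < 0:
                    raise ValueError("edge weights must be >= 0")
            asym = abs(adjacency - adjacency.T)
            if asym.nnz and asym.max() > 1e-12:
                raise ValueError("adjacency must be symmetric")
        adjacency.sum_duplicates()
        self.adjacency = adjacency
        self.node_names = node_names
        self.report: EdgeListReport | None = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges,
        node_names: list[str] | None = None,
    ) -> "Graph":
        """Build a graph from an iterable of ``(u, v, w)`` (or ``(u, v)``)."""
        rows, cols, vals = [], [], []
        for e in edges:
            u, v = int(e[0]), int(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if u == v:
                continue
            rows += [u, v]
            cols += [v, u]
            vals += [w, w]
        # coo->csr sums duplicate entries, which would double repeated edges;
        # collapse by max instead (order-independent)
        adj = _dedupe_max(rows, cols, vals, n_nodes)
        return cls(n_nodes, adj, node_names)

    # -- views -------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edges(self):
        """Yield each undirected edge once as ``(u, v, w)`` with ``u < v``."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for u, v, w in zip(coo.row, coo.col, coo.data):
            yield int(u), int(v), float(w)

    def edge_arrays(self):
        """Return ``(u, v, w)`` arrays, one entry per undirected edge, u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data

    def weight(self, u: int, v: int) -> float:
        return float(self.adjacency[u, v])

    def degrees(self) -> np.ndarray:
        """Weighted degree vector."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def total_weight(self) -> float:
        """Sum of all edge weights (each undirected edge counted once)."""
        return float(self.adjacency.sum()) / 2.0

    def has_edge(self, u: int, v: int) -> bool:
        return self.adjacency[u, v] != 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _dedupe_max(rows, cols, vals, n_nodes) -> sp.csr_matrix:
    """CSR from triplets keeping the max weight among duplicates."""
    if not rows:
        return sp.csr_matrix((n_nodes, n_nodes))
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    vals = np.asarray(vals, dtype=np.float64)
    key = rows.astype(np.int64) * n_nodes + cols
    order = np.lexsort((-vals, key))
    key, rows, cols, vals = key[order], rows[order], cols[order], vals[order]
    first = np.ones(len(key), dtype=bool)
    first[1:] = key[1:] != key[:-1]
    return sp.csr_matrix(
        (vals[first], (rows[first], cols[first])), shape=(n_nodes, n_nodes)
    )


@dataclass
class AttributeMatrix:
    """Dense N x F matrix of finite, non-negative node features."""

    values: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("attribute matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribute matrix contains NaN/Inf")
        if self.values.size and self.values.min() < 0:
            raise ValueError("attribute values must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# I/O


def read_edge_list(
    path, *, n_nodes: int | None = None, deduplicate: bool = True
) -> Graph:
    """Read a TSV edge list ``u<TAB>v[<TAB>w]`` into a :class:`Graph`.

    Self-interactions are dropped and duplicate pairs collapsed (keeping the
    maximum weight, which is order-independent); the counts of both removals
    are attached to the returned graph as ``graph.report``. ``(u, v)`` and
    ``(v, u)`` denote the same undirected edge. Lines starting with ``#`` and
    blank lines are ignored. A missing weight column defaults to 1.0.

    Node labels that are all non-negative integers are used as node ids
    directly (``n_nodes`` then defaults to ``max_id + 1``); otherwise labels
    are mapped to 0..N-1 in order of first appearance and kept as
    ``graph.node_names``.
    """
    raw: list[tuple[str, str, float]] = []
    report = EdgeListReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'u<TAB>v[<TAB>w]', got {line!r}"
                )
            try:
                w = float(parts[2]) if len(parts) > 2 else 1.0
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: bad weight {parts[2]!r}"
                ) from exc
            if not np.isfinite(w):
                raise GraphFormatError(f"{path}:{lineno}: non-finite weight")
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            raw.append((parts[0], parts[1], w))
            report.n_raw_lines += 1

    all_int = all(u.isdigit() and v.isdigit() for u, v, _ in raw)
    node_names: list[str] | None = None
    if all_int:
        ids = {lbl: int(lbl) for e in raw for lbl in e[:2]}
    else:
        ids = {}
        for u, v, _ in raw:
            for lbl in (u, v):
                if lbl not in ids:
                    ids[lbl] = len(ids)
        node_names = sorted(ids, key=ids.get)
    max_id = max(ids.values(), default=-1)
    if n_nodes is None:
        n_nodes = max_id + 1
    elif max_id >= n_nodes:
        raise GraphFormatError(
            f"node id {max_id} out of range for declared n_nodes={n_nodes}"
        )

    seen_directed: set[tuple[int, int]] = set()
    best: dict[tuple[int, int], float] = {}
    for u_lbl, v_lbl, w in raw:
        u, v = ids[u_lbl], ids[v_lbl]
        if u == v:
            report.n_self_loops += 1
            continue
        seen_directed.add((u, v))
        key = (min(u, v), max(u, v))
        if key in best:
            report.n_duplicates += 1
            if deduplicate:
                best[key] = max(best[key], w)
            continue
        best[key] = w

    report.n_unique_undirected = len(best)
    report.n_unique_directed = len(
        {(min(u, v), max(u, v)) for u, v in seen_directed}
    )
    g = Graph.from_edges(
        n_nodes, [(u, v, w) for (u, v), w in best.items()], node_names
    )
    g.report = report
    return g


def write_edge_list(g: Graph, path) -> None:
    """Write a graph as a TSV edge list, one undirected edge per line."""
    with open(path, "w") as fh:
        fh.write("# u\tv\tw\n")
        for u, v, w in g.edges():
            if g.node_names is not None:
                fh.write(f"{g.node_names[u]}\t{g.node_names[v]}\t{w:.12g}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.12g}\n")


def load_attributes(path, n_nodes: int) -> AttributeMatrix:
    """Load node attributes from MatrixMarket or dense TSV.

    The row count must equal ``n_nodes``; NaN/Inf entries are rejected.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(64)
    if path.endswith(".mtx") or head.startswith("%%MatrixMarket"):
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat)
    else:
        values = np.loadtxt(path, ndmin=2)
    if values.shape[0] != n_nodes:
        raise ShapeError(
            f"attribute matrix has {values.shape[0]} rows, graph has "
            f"{n_nodes} nodes"
        )
    return AttributeMatrix(values)


def save_attributes(attrs: AttributeMatrix, path) -> None:
    """Write attributes as MatrixMarket coordinate (``.mtx``) or dense TSV."""
    if str(path).endswith(".mtx"):
        scipy.io.mmwrite(str(path), sp.coo_matrix(attrs.values))
    else:
        np.savetxt(path, attrs.values, delimiter="\t", fmt="%.12g")


def read_compartments(path) -> dict[int, str]:
    """Read a ``node<TAB>compartment`` TSV into a node -> label mapping."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node<TAB>compartment'"
                )
            out[int(parts[0])] = parts[1]
    return out


def write_compartments(comp: dict[int, str], path) -> None:
    with open(path, "w") as fh:
        for node in sorted(comp):
            fh.write(f"{node}\t{comp[node]}\n")


# ---------------------------------------------------------------------------
# statistics


def density(g: Graph) -> float:
    """Graph density 2*|E| / N**2.

    The denominator is N squared (not N*(N-1)); this is the convention used
    for the published dataset statistics this package reproduces.
    """
    if g.n_nodes < 1:
        raise ValueError("density undefined for an empty graph")
    return 2.0 * g.n_edges / float(g.n_nodes) ** 2
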