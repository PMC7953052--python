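"""Random-walk corpus generation and skip-gram embedding training.

Two walk generators are provided on weighted graphs: first-order walks
(DeepWalk: the next node is a neighbour drawn proportionally to edge weight)
and second-order biased walks (Node2vec: the weight of each candidate step is
further multiplied by alpha = 1/p, 1 or 1/q according to whether the candidate
is the previous node, a neighbour of it, or neither). With p = q = 1 the two
transition laws coincide exactly.

The skip-gram model with negative sampling is trained here directly as
vectorized minibatch SGD on numpy arrays: pairs (center, context) are drawn
from each walk with a per-position random window, negatives from the 3/4-power
unigram distribution, and both input and output matrices are updated with
scatter-adds. A single seeded generator drives walk order, window draws,
shuffling and negative sampling, so corpora and embeddings are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .graph import Graph

__all__ = [
    "WalkConfig",
    "node2vec_alpha",
    "generate_walks",
    "train_skipgram",
    "embed_graph",
]


@dataclass
class WalkConfig:
    """Walk and skip-gram hyperparameters.

    Defaults: 10 walks of length 80 per node, return parameter p = 1.0 and
    in-out parameter q = 0.5, embedding window 10.
    """

    num_walks: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 0.5
    window: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.num_walks < 1:
            raise ParameterError("num_walks must be >= 1")
        if self.walk_length < 1:
            raise ParameterError("walk_length must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ParameterError("p and q must be > 0")
        if self.window < 1:
            raise ParameterError("window must be >= 1")


def node2vec_alpha(d_prev: int, cfg: WalkConfig) -> float:
    """Unnormalized bias for a candidate step at hop-distance d_prev from the
    previous node: 1/p if returning (d=0), 1 if staying adjacent (d=1), 1/q if
    moving away (d=2)."""
    if d_prev == 0:
        return 1.0 / cfg.p
    if d_prev == 1:
        return 1.0
    if d_prev == 2:
        return 1.0 / cfg.q
    raise ValueError(f"hop distance must be 0, 1 or 2, got {d_prev}")


def _neighbour_tables(g: Graph):
    a = g.adjacency
    return a.indptr, a.indices, a.data


def generate_walks(
    g: Graph, cfg: WalkConfig, mode: str = "node2vec"
) -> list[list[int]]:
    """Generate ``num_walks`` weighted random walks rooted at every node.

    Roots are visited in a fresh shuffled order on each pass. Isolated nodes
    emit the singleton walk ``[v]``. ``mode`` is ``"deepwalk"`` (first-order)
    or ``"node2vec"`` (second-order, biased by :func:`node2vec_alpha`).
    """
    if mode not in ("deepwalk", "node2vec"):
        raise ParameterError(f"unknown walk mode {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    indptr, indices, data = _neighbour_tables(g)
    second_order = mode == "node2vec" and (cfg.p != 1.0 or cfg.q != 1.0)

    walks: list[list[int]] = []
    for _ in range(cfg.num_walks):
        for root in rng.permutation(g.n_nodes):
            walk = [int(root)]
            prev = -1
            for _ in range(cfg.walk_length - 1):
                cur = walk[-1]
                lo, hi = indptr[cur], indptr[cur + 1]
                if hi == lo:
                    break
                nbrs = indices[lo:hi]
                w = data[lo:hi].astype(np.float64)
                if second_order and prev >= 0:
                    alpha = np.full(len(nbrs), 1.0 / cfg.q)
                    plo, phi = indptr[prev], indptr[prev + 1]
                    # neighbour index arrays are sorted in CSR form
                    common = np.isin(
                        nbrs, indices[plo:phi], assume_unique=True
                    )
                    alpha[common] = 1.0
                    alpha[nbrs == prev] = 1.0 / cfg.p
                    w = w * alpha
                cum = np.cumsum(w)
                nxt = int(nbrs[np.searchsorted(cum, rng.random() * cum[-1])])
                prev = cur
                walk.append(nxt)
            walks.append(walk)
    return walks


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


def _corpus_pairs(walks, window: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) pairs with a per-position window drawn from 1..window."""
    tokens = np.concatenate([np.asarray(w, dtype=np.int64) for w in walks])
    walk_id = np.concatenate(
        [np.full(len(w), i, dtype=np.int64) for i, w in enumerate(walks)]
    )
    b = rng.integers(1, window + 1, size=len(tokens))
    centers, contexts = [], []
    for delta in range(1, min(window + 1, len(tokens))):
        keep = (b[:-delta] >= delta) & (walk_id[:-delta] == walk_id[delta:])
        lhs, rhs = tokens[:-delta][keep], tokens[delta:][keep]
        # each qualifying (i, i+delta) yields both directed pairs
        centers.append(lhs)
        contexts.append(rhs)
        centers.append(rhs)
        contexts.append(lhs)
    if not centers:
        return tokens[:0], tokens[:0]
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(
    walks,
    n_nodes: int,
    dim: int = 128,
    window: int = 10,
    epochs: int = 5,
    neg_samples: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 4096,
) -> np.ndarray:
    """Train node vectors on a walk corpus; returns an n_nodes x dim matrix.

    Negative-sampling objective: for a (center c, context o) pair and noise
    nodes z_k, maximise log s(u_c.v_o) + sum_k log s(-u_c.v_{z_k}). Nodes that
    never appear in the corpus keep zero vectors. The learning rate decays
    linearly over all minibatches.
    """
    if not walks:
        raise ParameterError("corpus is empty")
    if dim < 1:
        raise ParameterError("dim must be >= 1")
    rng = np.random.default_rng(seed)

    counts = np.zeros(n_nodes, dtype=np.float64)
    for w in walks:
        np.add.at(counts, w, 1.0)
    present = counts > 0
    noise = counts**0.75
    noise /= noise.sum()

    centers, contexts = _corpus_pairs(walks, window, rng)
    n_pairs = len(centers)
    if n_pairs == 0:
        # corpus of singleton walks only: nothing to train against
        return np.zeros((n_nodes, dim))

    # minibatch updates are applied at stale parameters, so a node repeated
    # r times in a batch takes an r-fold step; cap the expected repetition
    # so eta * r stays inside the stable region even on tiny vocabularies
    n_present = int(present.sum())
    batch_size = max(64, min(batch_size, 32 * n_present))

    # float32 throughout the SGD loop: the updates are memory-bandwidth
    # bound and skip-gram is robust to single precision
    w_in = ((rng.random((n_nodes, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((n_nodes, dim), dtype=np.float32)
    w_in[~present] = 0.0
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    n_batches_total = epochs * int(np.ceil(n_pairs / batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            c, o = centers[idx], contexts[idx]
            bsz = len(idx)
            neg = np.searchsorted(
                noise_cdf, rng.random((bsz, neg_samples))
            )  # inverse-CDF draw from the unigram^0.75 distribution
            eta = np.float32(lr * max(1e-4, 1.0 - step / n_batches_total))
            step += 1

            h = w_in[c]  # (B, d)
            v_o = w_out[o]
            g_pos = _sigmoid(np.einsum("ij,ij->i", h, v_o)) - np.float32(1.0)
            grad_h = g_pos[:, None] * v_o
            v_n = w_out[neg]  # (B, K, d)
            g_neg = _sigmoid(np.einsum("ijk,ik->ij", v_n, h))  # (B, K)
            grad_h += np.einsum("ij,ijk->ik", g_neg, v_n)

            out_idx = np.concatenate([o, neg.ravel()])
            out_grad = np.concatenate(
                [
                    g_pos[:, None] * h,
                    (g_neg[:, :, None] * h[:, None, :]).reshape(-1, dim),
                ]
            )
            _scatter_add(w_out, out_idx, -eta * out_grad)
            _scatter_add(w_in, c, -eta * grad_h)
    w_in[~present] = 0.0
    return w_in.astype(np.float64)


def _scatter_add(target: np.ndarray, idx: np.ndarray, rows: np.ndarray):
    """target[idx] += rows with duplicate indices accumulated.

    Realized as a one-hot sparse matmul, which is much faster than
    np.add.at for wide rows.
    """
    r = len(idx)
    onehot = sp.csr_matrix(
        (
            np.ones(r, dtype=rows.dtype),
            np.asarray(idx, dtype=np.int32),
            np.arange(r + 1, dtype=np.int32),
        ),
        shape=(r, target.shape[0]),
    )
    target += onehot.T @ rows


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_graph(
    g: Graph,
    cfg: WalkConfig | None = None,
    mode: str = "node2vec",
    dim: int = 128,
    epochs: int = 5,
    neg_samples: int = 5,
) -> np.ndarray:
    """Walk + skip-gram in one call; returns the n_nodes x dim embedding."""
    cfg = cfg or WalkConfig()
    walks = generate_walks(g, cfg, mode=mode)
    return train_skipgram(
        walks,
        g.n_nodes,
        dim=dim,
        window=cfg.window,
        epochs=epochs,
        neg_samples=neg_samples,
        seed=cfg.seed,
    )
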