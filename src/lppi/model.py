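"""Estimator-style front ends composing the pipeline stages.

:class:`MultilevelEmbedding` is a transformer-like estimator (in the spirit of
sklearn's manifold learners): ``fit`` takes a graph plus optional node
attributes and exposes the refined node embedding as ``embedding_``.
:class:`LinkPredictor` stacks a logistic pair classifier on top and follows
the classifier protocol over node pairs. Both validate their parameters at
fit time, derive one seed per stage from ``random_state``, and support
``get_params``/``set_params`` so they compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .embedding import WalkConfig, generate_walks, train_skipgram
from .errors import ParameterError
from .fusion import FusionConfig, build_feature_graph, fuse
from .graph import AttributeMatrix, Graph
from .linkpred import (
    PairSet,
    edge_features,
    sample_negatives,
    train_classifier,
)
from .multilevel import Hierarchy, RefineConfig, build_hierarchy, refine_all

__all__ = ["MultilevelEmbedding", "LinkPredictor"]


class MultilevelEmbedding(BaseEstimator):
    """Fused, coarsened, walk-embedded and refined node representations.

    Parameters mirror the pipeline stages: fusion (``beta``, ``knn_k``),
    coarsening (``level``, ``t``, ``gs_iters``, ``sigma``), walks (``method``,
    ``num_walks``, ``walk_length``, ``p``, ``q``), skip-gram (``dim``,
    ``window``, ``epochs``, ``neg_samples``) and refinement (``power``).
    Defaults follow the reference configuration: 10 walks of length 80,
    dimension 128, p = 1.0, q = 0.5, beta = 0.1, one coarsening level.

    Attributes set by :meth:`fit`: ``embedding_`` (n_nodes x dim),
    ``hierarchy_``, ``achieved_level_``, ``fused_graph_``.
    """

    def __init__(
        self,
        beta: float = 0.1,
        knn_k: int = 10,
        level: int = 1,
        t: int = 16,
        gs_iters: int = 2,
        sigma: float = 1.0,
        method: str = "node2vec",
        num_walks: int = 10,
        walk_length: int = 80,
        p: float = 1.0,
        q: float = 0.5,
        dim: int = 128,
        window: int = 10,
        epochs: int = 5,
        neg_samples: int = 5,
        power: int = 2,
        random_state: int = 0,
    ):
        self.beta = beta
        self.knn_k = knn_k
        self.level = level
        self.t = t
        self.gs_iters = gs_iters
        self.sigma = sigma
        self.method = method
        self.num_walks = num_walks
        self.walk_length = walk_length
        self.p = p
        self.q = q
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.neg_samples = neg_samples
        self.power = power
        self.random_state = random_state

    def _stage_seed(self, stage: int) -> int:
        # one deterministic stream per stage, derived from the global seed
        return (int(self.random_state) + stage) % (2**31)

    def fit(self, graph: Graph, attributes: AttributeMatrix | None = None):
        """Embed every node of ``graph``; attributes are optional."""
        if not isinstance(graph, Graph):
            raise TypeError("fit expects a Graph")
        fused = graph
        if attributes is not None and self.beta > 0:
            if attributes.n_nodes != graph.n_nodes:
                raise ParameterError(
                    "attribute row count must match the node count"
                )
            feat = build_feature_graph(attributes, knn_k=self.knn_k)
            fused = fuse(
                graph, feat, FusionConfig(beta=self.beta, knn_k=self.knn_k)
            )
        self.fused_graph_ = fused

        hier = build_hierarchy(
            fused,
            level=self.level,
            t=self.t,
            gs_iters=self.gs_iters,
            seed=self._stage_seed(1),
            sigma=self.sigma,
        )
        self.hierarchy_ = hier
        self.achieved_level_ = hier.depth

        cfg = WalkConfig(
            num_walks=self.num_walks,
            walk_length=self.walk_length,
            p=self.p,
            q=self.q,
            window=self.window,
            seed=self._stage_seed(2),
        )
        walks = generate_walks(hier.coarsest, cfg, mode=self.method)
        e_coarse = train_skipgram(
            walks,
            hier.coarsest.n_nodes,
            dim=self.dim,
            window=self.window,
            epochs=self.epochs,
            neg_samples=self.neg_samples,
            seed=self._stage_seed(3),
        )
        self.embedding_ = refine_all(
            hier, e_coarse, RefineConfig(power=self.power, sigma=self.sigma)
        )
        return self

    def fit_transform(
        self, graph: Graph, attributes: AttributeMatrix | None = None
    ) -> np.ndarray:
        return self.fit(graph, attributes).embedding_


class LinkPredictor(BaseEstimator):
    """End-to-end link classifier over node pairs.

    ``fit`` embeds the graph with :class:`MultilevelEmbedding`, samples as
    many negative pairs as there are positive edges (respecting compartment
    exclusion when labels are given), and fits an L2 logistic regression on
    symmetric pair features. ``predict_proba`` scores arbitrary node pairs.
    """

    def __init__(
        self,
        operator: str = "hadamard",
        C: float = 1.0,
        random_state: int = 0,
        embed_params: dict | None = None,
    ):
        self.operator = operator
        self.C = C
        self.random_state = random_state
        self.embed_params = embed_params

    def fit(
        self,
        graph: Graph,
        attributes: AttributeMatrix | None = None,
        compartments: dict[int, str] | None = None,
    ):
        self.embedder_ = MultilevelEmbedding(
            random_state=self.random_state, **(self.embed_params or {})
        )
        emb = self.embedder_.fit_transform(graph, attributes)
        self.embedding_ = emb

        eu, ev, _ = graph.edge_arrays()
        negs = sample_negatives(
            graph, len(eu), comp=compartments, seed=self.random_state + 7
        )
        pairs = PairSet(
            np.concatenate([eu, negs.u]),
            np.concatenate([ev, negs.v]),
            np.concatenate([np.ones(len(eu), int), np.zeros(len(negs), int)]),
        )
        feats = edge_features(emb, pairs, self.operator)
        self.scorer_ = train_classifier(feats, pairs.labels, c=self.C)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, pairs: PairSet | np.ndarray) -> np.ndarray:
        pairs = self._as_pairs(pairs)
        p1 = self.scorer_(edge_features(self.embedding_, pairs, self.operator))
        return np.column_stack([1 - p1, p1])

    def predict(self, pairs: PairSet | np.ndarray) -> np.ndarray:
        return (self.predict_proba(pairs)[:, 1] >= 0.5).astype(int)

    @staticmethod
    def _as_pairs(pairs) -> PairSet:
        if isinstance(pairs, PairSet):
            return pairs
        arr = np.asarray(pairs)
        return PairSet(arr[:, 0], arr[:, 1], np.zeros(len(arr), int))
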