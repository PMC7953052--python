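"""Pair classification: negative sampling, pair features, metrics, and CV.

Positive examples are the observed interactions; negatives are node pairs
drawn from the complement graph, optionally excluding pairs whose proteins
share a cellular compartment (proteins confined to different compartments
are assumed not to interact, so such pairs are safe negatives). Two node
embeddings become one pair feature through a symmetric binary operator
(Hadamard product by default), and an L2-regularized logistic regression
scores the pair. Evaluation follows 5-fold cross-validation over the positive
edges with a fresh, equally sized negative set per fold, reporting accuracy,
sensitivity, precision, the Matthews correlation coefficient and rank-based
ROC AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .errors import CapacityError, ParameterError, ShapeError
from .graph import Graph

__all__ = [
    "PairSet",
    "ConfusionMetrics",
    "MetricsReport",
    "sample_negatives",
    "edge_features",
    "confusion_metrics",
    "auc",
    "train_classifier",
    "cross_validate",
]

PAIR_OPERATORS = ("hadamard", "average", "l1", "l2")

# rejection sampling gives up after drawing this multiple of the request
# and falls back to enumerating the complement explicitly
_OVERSAMPLE_CAP = 100


@dataclass
class PairSet:
    """Unordered labelled node pairs (u < v internally, labels in {0, 1})."""

    u: np.ndarray
    v: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.u) == len(self.v) == len(self.labels)):
            raise ShapeError("u, v and labels must have equal length")
        if np.any(self.u == self.v):
            raise ValueError("pairs must join distinct nodes")
        lo = np.minimum(self.u, self.v)
        hi = np.maximum(self.u, self.v)
        self.u, self.v = lo, hi

    def __len__(self) -> int:
        return len(self.u)


def _pair_keys(u: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(u, v).astype(np.int64)
    hi = np.maximum(u, v).astype(np.int64)
    return lo * n + hi


def sample_negatives(
    g: Graph,
    n: int,
    comp: dict[int, str] | None = None,
    seed: int = 0,
    exclude: PairSet | None = None,
) -> PairSet:
    """Draw ``n`` non-edges of ``g`` uniformly without replacement.

    If compartment labels are given, pairs whose endpoints share a
    compartment are ineligible (only cross-compartment pairs can be trusted
    as non-interactions). ``exclude`` removes additional pairs (e.g.
    negatives already drawn for another fold). Rejection sampling is used
    first; if it cannot fill the request the complement is enumerated
    exactly, and a :class:`CapacityError` reports the eligible count when
    even that falls short.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    nn = g.n_nodes
    rng = np.random.default_rng(seed)
    eu, ev, _ = g.edge_arrays()
    forbidden = set(_pair_keys(eu, ev, nn).tolist())
    if exclude is not None:
        forbidden |= set(_pair_keys(exclude.u, exclude.v, nn).tolist())
    comp_arr = None
    if comp is not None:
        cats = {c: i for i, c in enumerate(sorted(set(comp.values())))}
        comp_arr = np.full(nn, -1, dtype=np.int64)
        for node, c in comp.items():
            comp_arr[node] = cats[c]

    chosen: list[int] = []
    chosen_set: set[int] = set()
    drawn = 0
    while len(chosen) < n and drawn < _OVERSAMPLE_CAP * n:
        m = min(4 * (n - len(chosen)) + 16, _OVERSAMPLE_CAP * n - drawn)
        drawn += m
        u = rng.integers(0, nn, size=m)
        v = rng.integers(0, nn, size=m)
        ok = u != v
        if comp_arr is not None:
            same = (comp_arr[u] == comp_arr[v]) & (comp_arr[u] >= 0)
            ok &= ~same
        keys = _pair_keys(u, v, nn)
        for k in keys[ok]:
            k = int(k)
            if k in forbidden or k in chosen_set:
                continue
            chosen.append(k)
            chosen_set.add(k)
            if len(chosen) == n:
                break

    if len(chosen) < n:
        eligible = _enumerate_complement(g, comp_arr, forbidden)
        if len(eligible) < n:
            raise CapacityError(
                f"requested {n} negatives but only {len(eligible)} eligible "
                "non-edges exist",
                available=len(eligible),
            )
        chosen = list(rng.choice(eligible, size=n, replace=False))

    keys = np.asarray(chosen, dtype=np.int64)
    return PairSet(keys // nn, keys % nn, np.zeros(n, dtype=np.int64))


def _enumerate_complement(g, comp_arr, forbidden) -> np.ndarray:
    nn = g.n_nodes
    iu, iv = np.triu_indices(nn, k=1)
    keys = iu.astype(np.int64) * nn + iv
    ok = ~np.isin(keys, np.fromiter(forbidden, dtype=np.int64, count=len(forbidden)))
    if comp_arr is not None:
        same = (comp_arr[iu] == comp_arr[iv]) & (comp_arr[iu] >= 0)
        ok &= ~same
    return keys[ok]


def edge_features(
    emb: np.ndarray, pairs: PairSet, operator: str = "hadamard"
) -> np.ndarray:
    """Combine the two endpoint embeddings of each pair into one feature row.

    Operators (all symmetric in u, v): ``hadamard`` e_u * e_v; ``average``
    (e_u + e_v)/2; ``l1`` |e_u - e_v|; ``l2`` (e_u - e_v)^2.
    """
    if operator not in PAIR_OPERATORS:
        raise ParameterError(
            f"operator must be one of {PAIR_OPERATORS}, got {operator!r}"
        )
    emb = np.asarray(emb, dtype=np.float64)
    if len(pairs) and max(pairs.u.max(), pairs.v.max()) >= emb.shape[0]:
        raise IndexError("pair node id out of range for embedding")
    a, b = emb[pairs.u], emb[pairs.v]
    if operator == "hadamard":
        return a * b
    if operator == "average":
        return (a + b) / 2.0
    if operator == "l1":
        return np.abs(a - b)
    return (a - b) ** 2


@dataclass
class ConfusionMetrics:
    acc: float
    sen: float
    pre: float
    mcc: float
    zero_division: frozenset = field(default_factory=frozenset)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Accuracy, sensitivity, precision and MCC from a confusion matrix.

        Acc = (TP+TN)/(TP+TN+FP+FN)      Sen = TP/(TP+FN)
        Pre = TP/(TP+FP)                 MCC = (TP*TN - FP*FN)/sqrt(...)

    A metric whose denominator is zero is reported as 0 and named in
    ``zero_division``.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion matrix is empty")
    flags = set()
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn else flags.add("sen") or 0.0
    pre = tp / (tp + fp) if tp + fp else flags.add("pre") or 0.0
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else flags.add("mcc") or 0.0
    return ConfusionMetrics(acc, sen, pre, mcc, frozenset(flags))


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with half-credit for tied scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks resolve ties with half credit
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
        / (n_pos * n_neg)
    )


def train_classifier(features: np.ndarray, labels: np.ndarray, c: float = 1.0):
    """Fit an L2 logistic regression; returns ``scorer(features) -> P(link)``."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    model = LogisticRegression(C=c, max_iter=1000)
    model.fit(features, labels)

    def scorer(x: np.ndarray) -> np.ndarray:
        return model.predict_proba(np.asarray(x, dtype=np.float64))[:, 1]

    scorer.model = model
    return scorer


@dataclass
class MetricsReport:
    """Per-fold confusion counts and metrics, plus their means."""

    per_fold: pd.DataFrame

    @property
    def means(self) -> pd.Series:
        return self.per_fold.drop(columns="fold").mean()

    def to_frame(self) -> pd.DataFrame:
        """Fold rows plus an 'average' row, ready to serialize."""
        avg = self.means.to_frame().T
        avg.insert(0, "fold", "average")
        return pd.concat([self.per_fold, avg], ignore_index=True)


def cross_validate(
    g: Graph,
    emb_builder,
    comp: dict[int, str] | None = None,
    folds: int = 5,
    seed: int = 0,
    operator: str = "hadamard",
    threshold: float = 0.5,
    c: float = 1.0,
    inductive: bool = False,
) -> MetricsReport:
    """K-fold cross-validated link prediction on the positive edges of ``g``.

    Positive edges are split into ``folds`` near-equal parts. For each fold a
    fresh negative set the size of the whole positive set is drawn with a
    fold-derived seed (never colliding with any positive edge of the full
    graph) and split in proportion to the train/test positives; the
    classifier trains on the other folds' positives plus training negatives
    and is evaluated on the held-out positives plus test negatives.

    By default the embedding is built once on the full graph
    (transductive, matching the embed-then-evaluate protocol this package
    reproduces; held-out edges influence the embedding, which is optimistic).
    ``inductive=True`` re-embeds per fold with the test positives removed.
    """
    eu, ev, _ = g.edge_arrays()
    m = len(eu)
    if m < folds:
        raise ParameterError(f"need at least {folds} positive edges, have {m}")
    if comp is None:
        warnings.warn(
            "no compartment labels given; negative sampling will not apply "
            "the same-compartment exclusion",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    fold_idx = np.array_split(order, folds)

    emb_full = None if inductive else emb_builder(g)

    rows = []
    for k, test_ids in enumerate(fold_idx):
        train_ids = np.setdiff1d(order, test_ids, assume_unique=False)
        fold_seed = (seed + 1) * 1000 + k  # deterministic per-fold stream

        if inductive:
            mask = np.ones(m, dtype=bool)
            mask[test_ids] = False
            g_train = Graph.from_edges(
                g.n_nodes, zip(eu[mask], ev[mask]), g.node_names
            )
            emb = emb_builder(g_train)
        else:
            emb = emb_full

        negs = sample_negatives(g, m, comp=comp, seed=fold_seed)
        n_tr = len(train_ids)
        tr_pairs = PairSet(
            np.concatenate([eu[train_ids], negs.u[:n_tr]]),
            np.concatenate([ev[train_ids], negs.v[:n_tr]]),
            np.concatenate([np.ones(n_tr, int), np.zeros(n_tr, int)]),
        )
        n_te = len(test_ids)
        te_pairs = PairSet(
            np.concatenate([eu[test_ids], negs.u[n_tr : n_tr + n_te]]),
            np.concatenate([ev[test_ids], negs.v[n_tr : n_tr + n_te]]),
            np.concatenate([np.ones(n_te, int), np.zeros(n_te, int)]),
        )

        scorer = train_classifier(
            edge_features(emb, tr_pairs, operator), tr_pairs.labels, c=c
        )
        scores = scorer(edge_features(emb, te_pairs, operator))
        pred = (scores >= threshold).astype(int)
        y = te_pairs.labels
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        cm = confusion_metrics(tp, tn, fp, fn)
        rows.append(
            {
                "fold": k,
                "TP": tp,
                "TN": tn,
                "FP": fp,
                "FN": fn,
                "Acc": cm.acc,
                "Sen": cm.sen,
                "Pre": cm.pre,
                "MCC": cm.mcc,
                "AUC": auc(scores, y),
            }
        )
    return MetricsReport(pd.DataFrame(rows))
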