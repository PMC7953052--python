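"""Seeded synthetic attributed networks with planted community structure.

The generator emulates the shape of an attributed protein interaction
benchmark: a stochastic block model supplies the topology (dense within
functional modules, sparse across), block-correlated binary features stand in
for gene-set membership indicators, and the block labels double as cellular
compartments so compartment-filtered negative sampling can be exercised. All
draws come from a single seeded generator, so fixtures are reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .graph import AttributeMatrix, Graph

__all__ = [
    "SBMSpec",
    "AttributeSpec",
    "simulate_sbm",
    "simulate_attributes",
    "fixture_a",
]


@dataclass
class SBMSpec:
    """Stochastic block model: block sizes and intra/inter link probabilities."""

    block_sizes: tuple = (75, 75, 75, 75)
    p_in: float = 0.15
    p_out: float = 0.005
    seed: int = 7

    def __post_init__(self):
        if not all(s >= 1 for s in self.block_sizes):
            raise ParameterError("block sizes must be >= 1")
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ParameterError("p_in and p_out must lie in [0, 1]")


@dataclass
class AttributeSpec:
    """Binary block-indicator features.

    ``n_features`` columns are split evenly into one group per block; a
    feature owned by a node's block is on with probability ``signal``, any
    other feature with probability ``noise``.
    """

    n_features: int = 120
    signal: float = 0.6
    noise: float = 0.05
    seed: int = 7

    def __post_init__(self):
        if not (0 <= self.signal <= 1 and 0 <= self.noise <= 1):
            raise ParameterError("signal and noise must lie in [0, 1]")


def simulate_sbm(spec: SBMSpec) -> tuple[Graph, np.ndarray]:
    """Sample a stochastic block model; returns (graph, block label array)."""
    rng = np.random.default_rng(spec.seed)
    sizes = np.asarray(spec.block_sizes, dtype=np.int64)
    n = int(sizes.sum())
    labels = np.repeat(np.arange(len(sizes)), sizes)

    iu, iv = np.triu_indices(n, k=1)
    prob = np.where(labels[iu] == labels[iv], spec.p_in, spec.p_out)
    keep = rng.random(len(iu)) < prob
    adj = sp.csr_matrix(
        (np.ones(keep.sum()), (iu[keep], iv[keep])), shape=(n, n)
    )
    return Graph(n, adj + adj.T), labels


def simulate_attributes(
    labels: np.ndarray, spec: AttributeSpec
) -> tuple[AttributeMatrix, dict[int, str]]:
    """Block-correlated binary attributes and block-derived compartments."""
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    n_blocks = int(labels.max()) + 1
    if spec.n_features < n_blocks:
        raise ParameterError(
            f"need at least one feature per block "
            f"({spec.n_features} < {n_blocks})"
        )
    rng = np.random.default_rng(spec.seed)
    # feature f belongs to block owner[f]; groups as even as possible
    owner = np.repeat(
        np.arange(n_blocks),
        np.diff(np.linspace(0, spec.n_features, n_blocks + 1).astype(int)),
    )
    prob = np.where(
        labels[:, None] == owner[None, :], spec.signal, spec.noise
    )
    values = (rng.random((n, spec.n_features)) < prob).astype(np.float64)
    comp = {i: f"C{labels[i]}" for i in range(n)}
    return AttributeMatrix(values), comp


def fixture_a(seed: int = 7):
    """The canonical test network: 4 blocks x 75 nodes, p_in 0.15 / p_out
    0.005, 120 binary features at signal 0.6 / noise 0.05.

    Sized so a full fuse-coarsen-embed-refine-CV run stays around a minute
    on one core while link prediction is well above chance without being
    saturated. Returns (graph, attributes, block labels, compartments).
    """
    g, labels = simulate_sbm(SBMSpec(seed=seed))
    attrs, comp = simulate_attributes(labels, AttributeSpec(seed=seed))
    return g, attrs, labels, comp
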