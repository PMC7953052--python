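# lppi

Multilevel link prediction on attributed protein–protein interaction (PPI)
networks.

Experimentally mapped interactomes now reach hundreds of thousands of
interactions, and random-walk node embeddings (DeepWalk, Node2vec) — the
workhorse features for network-based interaction prediction — become the
bottleneck at that scale. `lppi` implements a multilevel scheme that makes
them fast without giving up accuracy, and augments topology with protein
attributes (e.g. binary gene-set membership indicators):

1. **Fusion.** Attributes induce a cosine-similarity graph on the same node
   set (sparsified to a symmetrized kNN graph); it is blended with the
   interaction topology as `A_fusion = A_topo + β·A_feat`.
2. **Spectral coarsening.** Random test vectors are low-pass filtered by
   Gauss–Seidel sweeps on the graph Laplacian; edges whose endpoints have
   nearly parallel smoothed signatures (spectral affinity
   `a_pq = ⟨K_p,K_q⟩² / (‖K_p‖²‖K_q‖²)` close to 1) are merged pairwise.
   The coarse adjacency is the Galerkin product `HᵀAH`, which conserves
   total edge weight. Repeating `l` times gives a hierarchy of shrinking
   graphs.
3. **Embedding.** The coarsest graph is embedded with weighted DeepWalk or
   Node2vec walks (second-order bias `1/p`, `1`, `1/q` by hop distance to
   the previous node) trained by skip-gram with negative sampling.
4. **Refinement.** Coarse embeddings are prolonged through `H` and smoothed
   with `(D̃^{-1/2}(A+σI)D̃^{-1/2})^k`, `D̃ = D + σI`, back to full
   resolution.
5. **Classification.** A pair `(u,v)` is featurized symmetrically from the
   two node vectors (Hadamard product by default) and scored by an
   L2-regularized logistic regression; negatives are non-edges drawn from
   the complement graph, excluding pairs that share a cellular compartment.
   Evaluation is 5-fold cross-validation with a fresh, equally sized
   negative set per fold, reporting Acc, Sen, Pre, MCC and ROC AUC.

The estimator front ends (`MultilevelEmbedding`, `LinkPredictor`) follow
scikit-learn conventions (`fit`, `fit_transform`, `predict_proba`,
`get_params`), and a `lppi` command line exposes each stage plus a one-shot
pipeline. A seeded synthetic generator (stochastic block model topology +
block-correlated binary attributes) makes the whole pipeline testable
without any downloads; the published SNAP PPI / GraphSAGE-PPI edge lists
are supported as optional inputs through the same TSV/MTX readers.

## Worked example

```sh
lppi simulate --preset fixture-A --out data/
lppi pipeline --edges data/edges.tsv --attrs data/attributes.mtx \
    --compartments data/compartments.tsv --seed 1 --out-dir run/
```

The first command writes a 300-node network (4 planted modules of 75
proteins, 1,837 interactions, density 0.0408) with 120 binary attribute
features. The second fuses, coarsens (300 → 153 nodes at level 1), embeds,
refines and cross-validates, printing the per-fold report:

```
   fold    TP    TN  FP   FN      Acc      Sen  Pre      MCC      AUC
      0 337.0 368.0 0.0 31.0 0.957880 0.915761  1.0 0.919027 0.992734
      1 334.0 368.0 0.0 34.0 0.953804 0.907609  1.0 0.911507 0.994706
      2 336.0 367.0 0.0 31.0 0.957766 0.915531  1.0 0.918815 0.993155
      3 334.0 367.0 0.0 33.0 0.955041 0.910082  1.0 0.913783 0.989836
      4 339.0 367.0 0.0 28.0 0.961853 0.923706  1.0 0.926406 0.993407
average 336.0 367.4 0.0 31.4 0.957269 0.914538  1.0 0.917908 0.992767
```

Each fold holds out one fifth of the known interactions plus an equal
number of sampled non-interacting, cross-compartment pairs. Mean AUC 0.993
means the ranking is nearly perfect; precision 1.0 with sensitivity 0.91
means every pair called an interaction at the 0.5 threshold was a true one,
at the cost of missing ~9% of held-out interactions. `run/` also contains
the coarse graphs, mapping operators, refined embedding and a JSON manifest
from which the run can be reproduced exactly.

The same thing in Python:

```python
import lppi

g, attrs, labels, comp = lppi.fixture_a(seed=7)
est = lppi.MultilevelEmbedding(random_state=1)          # β=0.1, l=1, d=128
report = lppi.cross_validate(
    g, lambda gr: est.fit_transform(gr, attrs), comp=comp, folds=5, seed=1
)
print(report.to_frame())
```

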