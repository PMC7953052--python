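# Methods

## Problem setting

Given an undirected weighted interaction network `G = (V, E)` over proteins
and, optionally, a non-negative attribute matrix `X ∈ R^{N×F}` (here: binary
gene-set membership indicators), the task is to decide for a candidate pair
`(u, v)` whether an interaction exists. The package treats this as
supervised classification over node pairs: known interactions are
positives, sampled non-edges are negatives, and the features of a pair are
derived from learned node embeddings.

## Graph model and conventions

Node ids are 0-based contiguous integers; string identifiers are mapped at
the I/O boundary and preserved for round-tripping. Self-interactions are
removed at load and duplicate records collapsed keeping the maximum weight
(an order-independent rule; the loader reports how many of each it
removed, plus the unique-pair count under both the directed-symmetrized and
undirected readings of the input, because published pair counts can follow
either convention). Graph density is computed as `2|E|/N²` — deliberately
with `N²` rather than the combinatorial `N(N−1)` — to match the convention
used by the benchmark statistics this package reproduces.

## Fusion

The attribute-similarity graph connects each node to its `knn_k = 10` most
cosine-similar other nodes (ties broken by ascending node id; zero-vector
rows contribute nothing; edge union symmetrization). Sparsification is a
scalability decision: exact all-pairs similarity is quadratic and is
retained only as a dense oracle in the tests (and used automatically below
2,000 nodes). Attributes enter raw — no TF-IDF or binarization — since the
intended inputs are already binary indicators. The fused adjacency is
`A_topo + β·A_feat` with default `β = 0.1`; similarity-only pairs become
new, down-weighted edges (the weighted-sum formula places no restriction to
existing links).

## Coarsening

Per level: `t = 16` standard-Gaussian test vectors are smoothed by 2
Gauss–Seidel sweeps of `L̃x = 0`, where `L̃` carries `σ = 1` self-loops so
the update `x_i ← (σx_i + Σ_j a_ij x_j)/(d_i + σ)` is defined on isolated
nodes. Two sweeps suffice because the merge criterion only needs the
low-frequency content, and keeping the pass linear in `|E|` is the point of
the scheme. After smoothing, the per-vector mean is removed: the constant
eigenvector survives any amount of smoothing and would otherwise push every
pairwise affinity toward 1.

Nodes are merged along edges only, pairwise (cluster size ≤ 2 per pass):
edges are ranked by spectral affinity descending with lexicographic
`(min id, max id)` tie-breaks, and an edge merges its endpoints iff both
are unmatched. The coarse adjacency is the Galerkin product `HᵀAH`; its
diagonal (intra-cluster weight) is dropped from the coarse graph because
self-loops are uninformative for random walks, but it is included in the
weight-conservation accounting (`sum(HᵀAH) = sum(A)`, tested to 1e-9). A
pass that shrinks the node count by less than 2% terminates the hierarchy
early and the achieved depth is recorded; with pairwise merging the
per-pass reduction is otherwise bounded by 2×.

The test-vector count, the refinement smoothing power and the embedding
dimension are three distinct parameters here (`t`, `power`, `dim`), even
though they play structurally similar "small dimension" roles.

## Embedding

Walks: `num_walks = 10` per node, length 80, roots shuffled per pass.
Transitions are proportional to edge weight (the fused and coarse graphs
are weighted; uniform steps would discard `β`'s effect). Node2vec applies
the second-order factor `1/p`, `1`, `1/q` for hop distance 0, 1, 2 to the
previous node, computed per step against the previous node's sorted
neighbour array; at `p = q = 1` the code short-circuits to the first-order
law, which the tests confirm is also the distributional limit of the biased
sampler. Isolated nodes emit singleton walks.

Skip-gram with negative sampling is trained in-package as vectorized
minibatch SGD: per-position windows drawn uniformly from `1..window`
(window 10), 5 negatives from the unigram^0.75 distribution via inverse-CDF
sampling, 5 epochs, initial learning rate 0.025 with linear decay, input
matrix initialized uniform `±0.5/dim`, output matrix zero. Updates are
applied per 4,096-pair minibatch with duplicate indices accumulated by a
one-hot sparse matmul; because accumulation multiplies the effective step
of a node repeated `r` times in a batch by `r`, the batch size is capped at
`32 × vocabulary` so `η·r` stays inside the stable region on heavily
coarsened graphs (unbounded accumulation demonstrably diverges there,
while per-node averaging under-trains — the cap keeps the summed-update
semantics that sequential SGD approximates). The loop runs in float32 (it
is memory-bandwidth bound; skip-gram is robust to single precision) and
results are returned as float64. Nodes absent from the corpus keep zero
vectors.

## Refinement

`Ê = (D̃^{-1/2}(A+σI)D̃^{-1/2})^k H E` per level, from the coarsest back to
level 0, with `k = 2` and `σ = 1` (the standard self-loop renormalization;
any small positive value only needs to keep `D̃` invertible). The operator
is symmetric with spectrum in `[−1, 1]`, so refinement never amplifies the
prolonged embedding; `k = 0` reduces to pure projection (each fine node
inherits its cluster's vector), which the tests use as an exact identity.

## Pair classification and evaluation

Pair features default to the Hadamard product of the endpoint embeddings —
the standard choice in the random-walk embedding literature when no
operator is prescribed — with `average`, `l1` and `l2` available; all four
are symmetric in `(u, v)`. The classifier is scikit-learn's L2 logistic
regression at default strength (`C = 1`), thresholded at 0.5.

Negative sampling draws uniformly from the complement graph, excluding
pairs whose proteins share a cellular compartment when labels are provided
(cross-compartment pairs are the trustworthy non-interactions); rejection
sampling is tried up to 100× oversampling, then the complement is
enumerated exactly, and a capacity error reports the eligible count when
the request cannot be met. Negatives never collide with any positive edge
of the full graph, not merely the training folds.

Cross-validation partitions the positive edges into 5 near-equal folds.
Per fold, a fresh negative set the size of the entire positive set is drawn
with a fold-derived seed and split in proportion to the train/test
positives, so the held-out fold is balanced. By default the embedding is
computed once on the full graph and reused across folds — the
embed-then-evaluate protocol this package reproduces. That protocol is
optimistic: held-out edges help shape the embedding. An `inductive=True`
mode re-embeds per fold with the test positives removed for honest
generalization estimates; the default is kept transductive for fidelity to
the reproduced protocol.

Metrics are computed from the confusion matrix exactly as conventionally
defined (Acc, Sen, Pre, MCC), with any zero-denominator metric reported as
0 and flagged; AUC is the rank-based Mann–Whitney statistic with
half-credit for ties, which the tests verify equals trapezoidal ROC
integration.

## Synthetic data

The generator emulates the *shape* of an attributed PPI benchmark, not its
biology: a stochastic block model stands in for functional modules, binary
block-correlated features for gene-set memberships, and block labels double
as compartments (so compartment-filtered negatives are inter-block). The
canonical network ("fixture-A") is 4 blocks × 75 nodes, `p_in = 0.15`,
`p_out = 0.005`, 120 features at signal 0.6 / noise 0.05, seed 7 — sized so
a full default run takes on the order of a minute on one core while link
prediction is clearly above chance without being saturated. What passing
tests on it show: the multilevel machinery preserves planted community
structure well enough for near-perfect pair ranking, degrades gracefully
with coarsening depth, and does not lose accuracy when informative
attributes are fused. What they do not show: behaviour under power-law
degrees, degree-assortativity, noisy/incomplete interactomes, or attribute
matrices whose correlation structure differs from block indicators — real
interactome properties the SBM does not model.

## Seeding and determinism

A single integer seed deterministically derives one stream per stage
(fusion is deterministic; coarsening, walks, skip-gram and sampling each
get `seed + stage index`), and per-fold negative seeds are derived from the
CV seed. Identical seeds give bit-identical hierarchies, corpora,
embeddings and reports (single-threaded).

## Known limitations

- The transductive default overstates performance relative to predicting
  truly unseen interactions (see above); use `inductive=True` for that
  question.
- Precision at the 0.5 threshold is frequently exactly 1.0 on
  well-separated data — the logistic scores of sampled negatives
  concentrate far below threshold — so Pre is a weak discriminator between
  configurations; AUC and MCC are more informative.
- Merging is restricted to cluster size 2 per pass; reaching a target graph
  size therefore takes ~log₂ levels, each with its own smoothing pass.
- The skip-gram trainer is optimized for the coarse graphs this pipeline
  produces (10²–10⁴ nodes per level); million-node corpora would want a
  compiled inner loop.
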