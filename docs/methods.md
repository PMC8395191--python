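# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not establish.

## Model

The data are a 0/1 association matrix `Y` (`Nc` circRNAs × `Nd` diseases)
and, optionally, a disease ontology (is-a DAG). The pipeline has three
stages — similarity integration, graph-attention encoding, pair
classification — trained end to end.

### Similarity integration

**Semantic similarity (SS).** Diseases are matched to ontology terms by
normalized name (trim, case-fold, collapse whitespace; no fuzzy matching).
For a disease term `t0`, every ancestor `t` receives a semantic value
`S(t) = max over upward paths of Δ^len(path)`, with `S(t0) = 1` and decay
Δ ∈ (0,1), default 0.5. Two diseases are scored by
`Σ_{t shared}(S_1(t)+S_2(t)) / (ΣS_1 + ΣS_2)`. This is the classic
DAG-decay (Wang-style) measure; the upstream description of the disease
similarity step names only a software package, not a measure, so the
concrete choice — and the decay value — are exposed as configuration.
Diseases absent from the ontology get an all-zero row and column
(diagonal included): integration then substitutes their interaction-profile
kernel, and the mapping report lists the unmatched names.

**Functional similarity (FS).** Best-match group averaging of SS between
the disease groups of two circRNAs. A circRNA whose disease group is empty
(possible inside cross-validation when its edges are masked) gets FS = 0
off-diagonal; diagonals of every similarity matrix are fixed to 1 before
integration, which keeps self-similarity consistent and is the standard
kernel convention. The formula is undefined at `|Di|+|Dj| = 0`, so the
zero-off-diagonal convention plus kernel fallback is the least-surprise
completion.

**GIP kernels (GC, GD).** Gaussian kernel on rows/columns of `Y` with
bandwidth `γ = 1 / mean squared profile norm`. An all-zero `Y` along an
axis is rejected (the bandwidth would divide by zero). Kernel diagonals are
exactly 1 and entries lie in (0, 1].

**Integration (SC, SD).** Cell-wise: the ontology/profile similarity where
it is nonzero, the kernel otherwise. SS and FS are typically sparse, so
this keeps their signal where it exists and falls back to the topology of
`Y` elsewhere.

### Graph-attention encoder

The bipartite graph has one undirected edge per known pair. Self-loops are
added to every node: isolated vertices otherwise have an empty
neighborhood and softmax attention would be undefined; with self-loops the
layer is total and isolated nodes simply retain (a transformed copy of)
their own features. Initial features are `X = [SC·MC ; SD·MD]` with
trainable projections `MC (Nc×F)`, `MD (Nd×F)`.

Per layer and head: edge scores
`e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j])` (negative slope 0.2, the convention
of the original graph-attention formulation), normalized by a
shift-by-max softmax over each in-neighborhood (the shift is constant per
neighborhood, so gradients are unchanged), then message aggregation
`Σ_j α_ij W h_j`. Layer width is constant at F: hidden layers run K heads
of width F/K and concatenate (hence F mod K = 0 there), the final layer
runs K heads of width F and averages them. The hidden nonlinearity is an
exponential-linear unit and the final layer is linear; both the head-width
reading and σ are under-determined upstream, and this is the only reading
consistent with concatenation *and* constant width. Both choices sit in
`EncoderConfig`. Parameters are Glorot-uniform initialized from the config
seed, so a (seed, data, config) triple fully determines the output.

### Classifier, sampling, loss and training

Pairs are scored by a 2-layer fully connected network on `concat(c, d)`
(input 2F, hidden F, LeakyReLU; scalar sigmoid output). Positives are the
training-fold `Y = 1` cells; an equal number of negatives (configurable
ratio) is drawn uniformly *once per fold* from the unknown cells,
excluding held-out test positives — drawing once keeps the train/test
protocol well defined, and nothing upstream suggests per-epoch resampling.

The loss is mean binary cross-entropy over the balanced samples plus
`λ‖Θ‖²` with Θ = every trainable tensor (projections, attention weights,
classifier). Two numerical points:

* The cross-entropy is computed in logit (softplus) form during training.
  On separable data sigmoid scores saturate to exact 0/1 in float64 and
  `log(score)` diverges; `mean(softplus(z) − y·z)` is the same function,
  computed stably.
* The penalty is applied in **decoupled (AdamW) form**: the data gradient
  goes through Adam's adaptive normalization, and the decay `2λ·lr·p` is
  applied directly to the parameters each step (clamped so the multiplier
  never goes negative). Routing `2λp` through Adam instead lets the
  constant decay direction dominate the normalized update and drags the
  jointly trained model into the all-zero stationary point — at zero, the
  balanced-batch cross-entropy gradient vanishes by symmetry, so the
  collapse is self-sustaining and the model degenerates to constant 0.5
  scores. Decoupling is the established remedy for exactly this Adam/L2
  pathology and reproduces the expected behavior that λ = 1e-2 is a good
  operating point rather than a destructive one. The reported loss trace
  is always the full objective (cross-entropy + λ‖Θ‖²).

Training is full batch (the problem is at most ~10⁵ pairs; no unstated
mini-batch size to guess), Adam step size 5e-3, 500 epochs by default —
sized so that a full curated-resource-scale run (≈585×88, ≈740 positives)
finishes a fivefold repeat in a few minutes on one CPU. Divergent
(non-finite) loss aborts with the epoch index. Gradients come from a small
reverse-mode tape (`autodiff.py`) written for exactly the operations this
model needs; its correctness is pinned by central-finite-difference tests
at 1e-4 relative tolerance.

### Evaluation protocol

The unit of cross-validation is the balanced sample (pair), split into k
disjoint folds of near-equal size — matching a protocol that splits "all
samples" rather than node sets. Within each fold the test positives' edges
are masked out of the graph before encoding (`mask_test_edges`, default
on). Whether the original experiments masked them is unstated; leaving
them in leaks test edges into the encoder, so masking is the default and
the flag documents the discrepancy. Classification threshold is 0.5
(threshold metrics only); AUC is the tie-aware rank statistic and AUPR the
step-interpolated precision–recall area (linear PR interpolation
overestimates). Repeats default to 10 in `RunConfig` terms but every
entry point takes `repeats` explicitly; the acceptance script uses one
repeat per seed across five seeds.

Ablations swap exactly one stage: `no_features` replaces the projected
similarities with fixed random-normal node features (projections drop out
of the parameter set), `no_gat` feeds concatenated similarity rows
directly to the classifier (no attention parameters), `no_nn` scores by a
sigmoid dot product of embeddings (no classifier parameters).

## Synthetic benchmark

`PlantedModel` draws a bipartite stochastic block model: circRNAs and
diseases carry latent blocks; `Y(i,j) ~ Bernoulli(p_in)` within blocks and
`Bernoulli(p_out)` across. The ontology is a rooted tree whose leaves are
the diseases, with one internal term per block, so same-block diseases
share a deeper ancestor — semantic, functional and kernel similarity all
align with the planted structure. All-zero rows/columns are redrawn (up to
100 attempts) so the kernels are defined; this conditions those profiles
on being nonempty, a negligible bias at the default densities.

Default instance: 60 circRNAs × 20 diseases, 4 blocks, p_in = 0.9,
p_out = 0.02, tree depth 4, branching 3 — dense enough that fivefold CV has
signal in every fold, small enough that a full masked CV run takes tens of
seconds. The resource-scale check uses 585 × 88, 8 blocks, p_in = 0.06,
p_out = 0.001, giving ≈800 positives.

**What passing on this benchmark shows — and does not.** It shows the
pipeline recovers block-structured association signal end to end through
masking, training and ranking. It does not emulate real curated resources:
no long-tail degree distribution (most real circRNAs have exactly one
association), no name noise, no ontology depth heterogeneity, and block
structure is a much cleaner signal than real disease modules. Results on
real data will be materially harder, and headline metrics from curated
datasets are not comparable to the synthetic numbers.

## Degenerate inputs and tie-breaks

Cyclic ontologies are rejected with the offending cycle; dangling is-a
edges are dropped with a warning; obsolete terms are skipped. Duplicate
association rows are deduplicated (count logged). Rankings sort by
descending score with ties broken by circRNA name, so output files are
byte-stable. Single-class test folds (possible at k near the sample count)
report threshold metrics only, since AUC/AUPR are undefined there.

## Known limitations

* Transductive only: a circRNA or disease absent from `Y` at training time
  has no embedding (new-node inference is out of scope).
* Disease–ontology matching is exact after normalization; synonym tables
  are not consulted.
* Negative "samples" are unverified unknowns, not true negatives; the
  sampling bias this introduces is inherent to the protocol.
* Dense matrices throughout — appropriate up to a few thousand entities,
  not beyond.
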