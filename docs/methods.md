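# Methods

## Problem and pipeline

`mdlink` scores candidate miRNA–disease pairs by combining *attribute*
features (sequence- and ontology-derived similarity) with *behaviour*
features (graph-embedding of a heterogeneous molecular association
network, MAN).  The MAN is an undirected binary graph over five node types
(miRNA, lncRNA, protein, disease, drug) and nine association types; its
miRNA–disease edges double as the positive labels of the link-prediction
task.

Stages: (1) CGR descriptors → miRNA similarity matrix; (2) MeSH-DAG
semantic similarity → disease similarity matrix; (3) SDNE embedding of the
MAN adjacency → 128-dim behaviour vectors; (4) stacked-autoencoder
compression of each similarity row → 64-dim attribute vectors;
(5) concatenation into 384-long pair descriptors
[M_b | M_sim | D_b | D_sim] with boundaries (0, 128, 192, 320, 384);
(6) 1-D CNN classification; (7) leakage-controlled five-fold cross
validation, or full-data training plus per-disease candidate ranking.

## Chaos game representation

The iteration is the standard bounded contraction
T_i = T_{i−1} + c·(G_i − T_{i−1}) from T_0 = (0.5, 0.5) with c = 0.5.
(The superficially similar form T_{i−1} + c·(T_{i−1} − G_i) is divergent —
|T_i| grows without bound — and would make a fixed spatial partition
meaningless, so the contraction toward the corner is the only reading
consistent with a bounded 8×8 summary.)  Cells are half-open
[k/8, (k+1)/8); a coordinate of exactly 1.0 clamps into the last
row/column (points never reach 1.0 for valid c, so this only guards the
public `subspace_index` helper).  Z is the *population* z-score (ddof 0)
of the 64 cell counts; when all counts are equal the z-scores are defined
as 0.  T is accepted as U and case is ignored, since FASTA sources vary.
Similarity is the ordinary Pearson correlation of the flattened
(X, Y, Z)-per-cell vectors; a zero-variance descriptor raises rather than
returning a silent default.

## Disease semantics

Ancestors come from tree-number prefix truncation (the standard MeSH
convention).  A term present at several depths takes the maximum decayed
contribution (deepest-first memoised traversal), with decay ϑ = 0.5.
Diseases without tree numbers receive self-only DAGs — similar only to
themselves — with a logged warning, rather than being dropped; this keeps
the labeled set and the similarity matrix index-aligned.

## Network embedding (SDNE)

Mirrored dense autoencoder on adjacency rows; combined objective

    L = ‖(X̂ − X) ⊙ B‖²_F + α Σ_ij s_ij ‖y_i − y_j‖² + ν L_reg,

with b_ij = β for nonzero entries (β = 5), α = 0.05, ν = 1e-4,
L_reg = ½ Σ_k (‖W(k)‖² + ‖Ŵ(k)‖²).  Encoder sizes N → 512 → 128, sigmoid
units, sigmoid decoder output (adjacency entries are binary).  Training is
mini-batch Adam (batch 64, full-batch fallback for tiny networks); the
first-order term uses the adjacency sub-block of each batch, so each
undirected edge contributes twice when both endpoints share a batch.

Numerical choices that matter:

* **Gradient scaling.** The losses are sums (not means), so mini-batch
  gradients are divided by the batch size before the Adam step; without
  this the effective step size scales with the data and the sigmoid stack
  saturates to a binary code that loses neighbourhood structure.
* **Epochs 100, lr 0.005.**  At 50 epochs the embedding demonstrably
  underfits some cross-validation folds of the default test world (planted
  block separability 0.88 vs 1.00 at 100 epochs); at lr 0.01 training
  saturates.  Both are exposed in `SdneConfig`.
* Gradients are verified against central finite differences to 1e-4
  relative error in the test suite.

`epochs = 0` returns the untrained forward pass, which makes the training
contract itself testable.

## Attribute compression

Each similarity matrix row is compressed n → 256 → 64 by a mirrored
autoencoder with sigmoid hidden units and a **linear** output layer
(similarity entries can be negative; a sigmoid decoder could not
reconstruct them).  Matrix columns are z-scored (statistics from the
fitted rows) before training: raw similarity rows cluster tightly around
their column means and reconstruct trivially, which loses the row identity
the downstream classifier needs — with z-scoring, the compressed codes of
the default test world separate planted blocks perfectly.  Per CV fold the
autoencoder is fitted on rows of entities appearing in training pairs and
applied to all entities; the similarity matrices are label-free, so no
label leakage arises.

## Classifier

1-D CNN over the 384-long descriptor as a single-channel sequence:
conv(32, 3×1) → ReLU → conv(64, 3×1) → ReLU → maxpool(2×1) → flatten →
dense(128, ReLU, dropout 0.5) → softmax(2).  Valid padding, stride 1.
Inputs are standardised per feature on training statistics (stored in the
fitted model); head layers are initialised small so initial logits are
near zero — without both, training on near-binary saturated descriptors
collapses to a constant predictor.  Adam (lr 1e-3, batch 64, 60 epochs,
step decay ×0.3 at 60% and 85% of the budget).  Implemented in float32
with analytic gradients.

`baseline_classifiers()` exposes Bagging, LogisticRegression, GaussianNB,
AdaBoost and MLP (scikit-learn) behind the same fit/predict_proba
contract, so the CV harness runs unchanged with any registry entry.

## Evaluation protocol

Positives are randomly partitioned into five folds.  Per fold: test-fold
miRNA–disease edges are removed from the MAN (both orientations) before
the embedding is fitted; all other edge types stay intact.  Train and test
negatives are disjoint uniform samples of unknown pairs at ratio 1:1 with
the positives (negative construction is not prescribed by the protocol
this follows; uniform sampling is the field's standard).  Confusion-based
metrics use threshold 0.5; AUC is the rank-based (Mann–Whitney)
statistic with tie correction; AUPR is average precision.  A programmatic
audit asserts, per fold, that no test positive survives as an edge in the
embedded network nor appears among training rows.  MCC with a degenerate
confusion matrix is defined as 0.

Case-study mode (`fit_full` + `rank_candidates`) trains on *all* known
pairs — including attribute compression on the full data — and ranks every
miRNA not yet associated with the query disease, ties broken
lexicographically by id.

## Synthetic world

The generators emulate the real inputs with a planted, recoverable signal:
nodes of every type are split into 3 blocks; miRNA–disease edges appear
with p_in = 0.3 within matched blocks and p_out = 0.02 across; the other
eight association types use densities 0.08 (within) / 0.01 (across),
chosen as a sparse-but-connected regime typical of curated interaction
databases; same-block miRNAs share a planted 6-mer motif in otherwise
random 20–25 nt sequences; each block's diseases occupy a private branch
of a depth-≤4 tree-number hierarchy.  Default scale 60/40/50/30/30 nodes.
Every output is a pure function of (spec, seed).

What a green end-to-end test establishes — and what it does not: the
generator produces exchangeable Bernoulli edges given blocks, so the only
learnable signal is block membership.  Real association data has degree
heterogeneity, overlapping communities and annotation biases that this
world does not emulate; a green test shows the pipeline recovers planted
community structure without leakage, not that it attains any particular
performance on real databases.

An intrinsic consequence of the stated world: some positives are
cross-block (≈12% at the defaults) and some uniformly sampled unknown
negatives are within-block (≈26%), and neither is distinguishable from
the opposite class by any method.  The Bayes-optimal scorer (the true
block-match oracle) achieves mean five-fold AUC ≈ 0.82 at the default
parameters; measured pipeline AUC should be read against that ceiling,
not against 1.0.

## Known limitations

* Dense adjacency (fine to ~10⁴ nodes; the real-scale MAN of ~6.5k nodes
  fits comfortably, but the implementation is not tuned for much larger
  graphs).
* The CNN underperforms a plain MLP slightly on block-structured synthetic
  descriptors (weight sharing across descriptor positions is mismatched to
  position-specific features); the registry makes swapping classifiers
  trivial.
* No GPU path; all networks are single-threaded numpy.
* Loaders expect pre-extracted TSV/FASTA inputs; no parsing of source
  database formats, and no mapping of disease names to MeSH headings.
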