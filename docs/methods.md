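# Methods

## Model

`cellont` treats cell type annotation as classification over the label
graph of a cell-type ontology rather than over a flat label set. Three
assumptions carry the method:

1. **The ontology graph reflects biological similarity** — terms close on
   the `is_a` graph describe transcriptionally similar cells
   (guilt-by-association). This is what justifies transferring probability
   mass from seen to unseen terms along edges.
2. **Term descriptions reflect the same similarity** — text-description
   cosine similarity correlates with graph proximity, so it can both
   weight existing edges and add edges the ontology is missing.
3. **A low-rank embedding of graph diffusion preserves what matters** —
   the random-walk equilibrium distributions are smooth over the graph,
   so a rank-q SVD of their seen-term block loses little.

### Stage 1 — label harmonization

Term definitions (the `def:` sentence, falling back to the term name) and
user labels are embedded by a pluggable deterministic text encoder. The
default is a hashed character 3-gram frequency vector (dimension 512,
CRC32 bucketing, L2-normalized). It is not a neural sentence encoder and
does not capture synonymy beyond surface form; it was chosen because it
is dependency-free, bitwise reproducible, and because everything
downstream consumes only cosine geometry, so any encoder implementing
`encode(text) -> unit vector` can be swapped in. Each label maps to its
most similar term; optional maximum-weight bipartite matching
(networkx blossom algorithm, exact) makes the assignment injective, which
resolves collisions between near-duplicate sibling descriptions.

### Stage 2 — graph embedding

With P the row-normalized weighted adjacency of the undirected working
graph and α the restart probability, the diffusion matrix is the closed
form S = α(I − (1−α)P)⁻¹; rows are probability distributions. Isolated
nodes are given a self-transition so S stays row-stochastic. Dense solve
up to 2,000 nodes; above that, iterative propagation
x ← αe + (1−α)xP to tolerance 1e-8 (max 1,000 iterations).

Only seen terms are embedded: the seen block of S is symmetrized as
(S + Sᵀ)/2 and factored by SVD, E = U_q√Σ_q. Embedding seen terms only
keeps the representation compact and sidesteps fitting parameters for
labels with no data; unseen terms enter through propagation instead
(stage 3). Default q = min(500, n_seen − 1); requests above n_seen are
clipped with a warning.

### Stage 3 — classification and propagation

Term features are X = [E | I]; the identity block plays the role of a
per-term bias and eases optimization. The classifier scores cell i
against term j by ReLU(ReLU(M_i W₁)W₂)X_jᵀ and is trained with softmax
cross-entropy over the seen terms. The softmax is restricted to seen
terms (c_out = n_seen) — unseen columns of the label matrix are all zero
and carry no gradient, so including them would only dilute the softmax;
mass reaches unseen terms exclusively through the diffusion step
score(i, t) = Σ_s P(i, s)·S(s, t). Propagated rows are renormalized to
the simplex; since all evaluation metrics are rank-based, normalization
affects presentation, not ranking within a cell.

Twelve models — d_c ∈ {2, 3, 4} (edge-augmentation cutoff; d_c = 2 adds
nothing) crossed with α ∈ {0.5, 0.6, 0.7, 0.8} — are averaged
elementwise. Averaging over graph variants and diffusion locality levels
is the method's robustness mechanism; any single member is usable alone.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| restart probability α | {0.5, 0.6, 0.7, 0.8} | walk locality; ensemble covers a range rather than tuning one value |
| edge cutoff d_c | {2, 3, 4} | max hop distance (exclusive) for text-similarity edges; 2 = original graph |
| text-similarity threshold | 0.8 | minimum cosine for a new edge |
| embedding rank q | min(500, n_seen − 1) | diffusion block is smooth; full rank is never needed |
| hidden width h | 5 | deliberately small — real datasets may have very few seen types |
| learning rate / epochs | 1e-2 / 300 full-batch ADAM passes | chosen once for reliable convergence on the linearly separable toy and the standard synthetic dataset; exposed in `AnnotatorConfig`. Datasets above 10,000 cells switch to mini-batches of 128 |
| marker threshold | 0.4 | signed Spearman ρ; only positive correlations are markers |
| preprocessing trim | 1% | per-gene mean log expression, fit on training data only |

## Synthetic data generator

The generator produces the conditions the method relies on, not realistic
scRNA-seq: a rooted `is_a` tree whose definition sentences share phrase
stems along ancestry (so text similarity tracks graph proximity);
per-term gene signatures — gamma background plus a few elevated genes —
smoothed along the graph as sig ← (1−β)·sig + β·neighbor-mean for three
rounds (β = 0 gives independent types; the standard dataset uses
β = 0.5); and Poisson counts with lognormal per-cell depth (σ = 0.1 ×
noise; noise = 0 returns signatures verbatim for exact-output tests).
The standard dataset is a 40-term binary tree, 120 genes, 30 cells per
term, with cells sampled only at the 20 leaves so labels are mutually
exclusive by construction. All draws derive from a single numpy PCG64
seed.

What passing tests therefore show: the pipeline correctly exploits
graph-correlated expression to rank unseen types, and every numerical
contract holds. What they do not show: robustness to dropout, batch
effects, ambient RNA, imbalanced type abundances, or misannotation —
none of which the generator emulates.

## Numerical choices

- RWR uses the closed-form inverse below 2,000 nodes (exact to machine
  precision, verified against iterative propagation at 1e-6), iterative
  solve above.
- SVD symmetrization (S + Sᵀ)/2 before factoring; the seen block of S is
  similar to a positive-definite matrix for connected graphs, and E·Eᵀ
  reconstructs the symmetrized block to 1e-6 at full rank on test graphs.
- Weight initialization: uniform(−1/√fan_in, 1/√fan_in), seeded; zero
  initialization is available and yields exactly uniform predictions
  (used as an analytic test anchor). Training is deterministic per seed.
- AUPRC is the trapezoidal integral of the precision–recall curve. The
  average-precision step estimator carries an upward small-sample bias
  (~0.012 at 100 positives + 300 negatives) that would distort the
  1:3-subsampled random baseline of 0.25; the trapezoidal estimator sits
  within 0.005 of it.
- Negative subsampling for AUPRC is per class and seeded; classes short
  of 3× negatives use all negatives.
- Ties: Spearman uses average ranks, and constant vectors get ρ = 0
  (conservative: never a marker) instead of NaN. Top-k ranking and
  nearest-unseen assignment break ties by ascending term index / id.
- Degenerate inputs: empty gene intersection, all-zero label rows,
  non-finite losses, and zero diffusion rows raise; off-simplex score
  rows and missing marker genes warn and recover.

## Design decisions taken where the design was open

- **Edge weights enter the walk** through row normalization of the
  weighted adjacency, so text similarity biases transition probabilities.
- **Softmax over seen terms only**, matching the seen-only embedding;
  scoring all terms would assign arbitrary logits to untrained rows of X.
- **Propagated scores are renormalized** rather than left as raw
  diffusion mass (rank metrics are unaffected; rows stay interpretable).
- **1% trimming is per-gene** (mean log expression), not per-entry; a
  per-entry reading would destroy matrix rectangularity. Boundary ties
  resolve by gene id.
- **Obsolete ontology terms are dropped** at parse time; only `is_a`
  relations are used (`part_of`, `develops_from` ignored).
- **Synonym lines in OBO input are ignored** for text similarity; only
  the `def:` sentence (or name) feeds the encoder.
- **Free-text mapping exposes `top_k` and refinement as configuration**;
  nearest-term is the default and bipartite matching is opt-in, since
  injectivity is only correct when the label set is known to be
  duplicate-free.

## Limitations

- The default text encoder is surface-form only; "NK cell" and "natural
  killer cell" are close, but true synonyms with disjoint spelling need a
  pretrained sentence encoder dropped into the same interface.
- Propagation transfers mass to unseen terms near seen ones; terms far
  from every seen term receive near-uniform mass and rank poorly.
- The trainer is plain numpy ADAM: fine for 10⁴–10⁵ cells, not tuned for
  atlas-scale data or GPUs.
- The no-rejection design means every cell is assigned somewhere;
  out-of-ontology cells (doublets, debris) are not flagged.
- Evaluation problem sizes in tests and the acceptance script (40-term
  ontology, hundreds of cells, five replicate splits) are the package's
  desk-scale defaults; conclusions about atlas-scale behavior require
  atlas-scale data.
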