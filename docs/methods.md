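# Methods

## Problem and model

`dgcgrn` infers a directed gene regulatory network (GRN) from a gene ×
sample expression matrix, a set of known regulations (gold standard), and
optionally gene sequences.  Inference is cast as directed link prediction:
given node features and a message-passing graph built from known training
edges, the model scores every queried ordered pair (i, j) with the
probability that gene i regulates gene j.

### Directed graph convolution

A directed graph G = (V, E) with weighted adjacency A is summarised by
three symmetric proximity matrices:

- first order: `A_F = sym(A)` (elementwise max of A and Aᵀ);
- second-order in: `A_Sin(i,j) = Σ_k A[k,i]·A[k,j] / Σ_v A[k,v]` — shared
  regulators, each mediator k normalised by its total out-weight;
- second-order out: `A_Sout(i,j) = Σ_k A[i,k]·A[j,k] / Σ_v A[v,k]` — shared
  targets.

Mediators with zero normaliser are skipped (0/0 := 0): a node with no
out-edges cannot mediate shared-regulator proximity.  The diagonal is
computed by the same sums and not zeroed; self-loops enter once through
normalisation, `D̃^{-1/2}(M + I)D̃^{-1/2}` with D̃ the row sums of M + I.
The normalised matrix always has top eigenvalue exactly 1, which bounds the
spectral gain of each convolution.

One layer computes `Z_b = norm(A_b) X Θ_b` per branch and fuses
`relu([Z_F ‖ α·Z_Sin ‖ β·Z_Sout])`; two layers are stacked.  The mixing
scalars α, β default to 1; setting both to 0 with a symmetrised adjacency
reduces the model to an ordinary undirected GCN (the ablation baseline).
Θ is per-branch by default; `share_theta` ties the three branches (the
literature is ambiguous on whether the convolution weight is shared).

An ordered pair is scored by a two-layer feed-forward head on the
concatenation (h_i ‖ h_j) with a logistic output.  Concatenation rather
than an inner product is deliberate: inner-product heads are symmetric and
cannot represent the direction of regulation.

### Local augmentation (CVAE)

Many genes in a GRN have degree 1, giving the convolution almost nothing to
aggregate.  A conditional VAE learns the distribution of neighbour features
X_u conditioned on the central node's features X_v over all (neighbour,
centre) incidences of the training graph (direction ignored, both
orientations collected).  Encoder and decoder are two-layer MLPs; the loss
is squared reconstruction error plus the closed-form KL to N(0, I).  After
training, one vector per node is generated by decoding (z ~ N(0, I), X_v)
with a single seeded draw per run, and concatenated to the node's features
(width `d_gen`, default 50).

When `d_gen` differs from the raw feature width, the reconstruction target
is X_u mapped through a fixed, seeded orthonormal random projection into
the `d_gen`-dimensional space (identity when widths match, zero-padding
when `d_gen` is larger).  This keeps the evidence bound well defined at any
generated width while preserving as much of the neighbour signal as a
linear sketch can.  The CVAE sees only node features and training-graph
structure, never edge labels; because it is fit transductively on all
nodes' features, a mild feature-leakage channel exists in principle and is
accepted as a design trade-off.

### Sequence features

Two complementary representations, used only when sequences are supplied:

1. **Physicochemical descriptors** (25 values per gene): normalised Z-curve
   endpoint (3), GC content, AT/GC ratio (with a +1 pseudocount in the
   denominator when GC = 0, which real genes essentially never trigger),
   mononucleotide composition (4), and adjacent-dinucleotide composition
   (16).  `N` bases are excluded from every count.
2. **Hidden features**: overlapping 5-mers (stride 1) are mapped to integer
   tokens over the 4⁵ + 1 vocabulary (any `N`-containing 5-mer is the
   unknown token; token identity embedding is mathematically one-hot ×
   matrix, just narrower in memory), padded/truncated to the 95th
   percentile of token counts, and encoded by a bidirectional GRU (hidden
   32 per direction) whose final states are projected to 60 features.  The
   encoder is trained jointly with the link-prediction loss; there is no
   separate sequence objective.

### Dynamic update

After a warm-up (default 10 epochs), the model's current dropout-free edge
probabilities replace the training-graph edge weights every epoch, and all
three proximity matrices are rebuilt before the next epoch.  Only training
edges are ever re-weighted — test edges never touch the message-passing
graph, so the update cannot leak labels.

### Training and evaluation protocol

Binary cross-entropy (computed in logit space for stability) with Adam at
learning rate 1e-3, dropout 0.5 between layers, 200 epochs by default.
Negatives are uniformly sampled ordered non-edges at ratio 1:1, with
reversed positives eligible (direction is part of the task); samples are
redrawn per repeat.  Evaluation is repeated k-fold cross-validation
(default 10 × 5-fold): positives are partitioned, the fold's message graph
is built from training positives only, and AUROC (tie-averaged rank
statistic) plus AUPR (average precision) are threshold-free; confusion
counts use threshold 0.5, which the underlying metric definitions need but
never pin down.

All trainable components run on a small in-repo reverse-mode autodiff
engine over float64 numpy (`autodiff.py`) with Glorot initialisation; every
random draw flows from explicit `numpy` generators, so any run is
reproducible bit-for-bit from its seed.

## Synthetic benchmark

The generator produces complete instances at the scale of the classic
in-silico benchmarks: 100 genes, 210 samples, 176 known regulations by
default.

- **Graph**: nodes are ordered with transcription factors (25% of genes)
  first; edges run from lower to higher index (hence acyclic) and attach
  preferentially to TFs with high out-degree, giving a scale-free out-degree
  profile.  A configurable fraction of nodes (default 30%) is forced to
  total degree 1 to reproduce the low-degree regime that motivates
  augmentation.
- **Expression**: regulator-free genes draw from N(0, 1); a regulated gene
  is a centred logistic of the signed weighted sum of its regulators
  (|w| ∈ [1, 2.5]) scaled to roughly unit range, plus N(0, 0.1) noise.
- **Sequences**: lengths uniform in [150, 250]; TF sequences draw bases at
  GC 0.55 versus 0.45 for the rest, planting a weak, recoverable
  compositional signal for the sequence branch.  A mutation operator
  substitutes each site independently at a given rate.

What the generator does **not** emulate: realistic expression dynamics
(time series, perturbations), feedback loops, realistic promoter/motif
structure in sequences, and measurement-specific noise.  Passing tests on
these fixtures therefore demonstrate that the implementation recovers the
kind of structure it assumes, not that it matches published performance on
real organisms.

## Problem sizes used in the automated checks

The test-suite and acceptance-script runs use the default benchmark scale
with 5 generator seeds, one repeat of 5-fold cross-validation per seed,
60 training epochs (40 when the Bi-GRU is trained jointly, with token
length capped at 150), and 150 CVAE epochs — sizes chosen so the planted
structure is comfortably recoverable while a full run stays fast on one
CPU.  The augmentation comparison additionally runs at 30 expression
samples, the low-information regime local augmentation targets (real
compendia in this field often provide only a few dozen conditions).

## Numerical and degenerate-input choices

- Second-order products and the symmetric normalisation are symmetrised
  exactly (`(S + Sᵀ)/2`) to remove last-ulp floating-point asymmetry.
- Ties in ranked predictions are broken lexicographically by (source,
  target); AUROC uses tie-averaged ranks.
- Sequences shorter than k yield no tokens; such genes get a zero Bi-GRU
  vector (with a warning) and genes without any sequence get a zero
  descriptor block, so missing sequences never drop genes.
- Gold-standard rows labelled 0 (known negatives) are parsed and exposed
  but unused by default (`keep_known_negatives`), since it is unclear
  whether published protocols treat them as negatives or discard them.
- Degenerate inputs raise early: empty training pair sets, one-class test
  sets, non-finite losses, scores outside (0, 1) in the dynamic update.

## Known limitations

- Full-graph training only; no minibatched neighbour sampling.  Fine at
  the hundreds-to-thousands-of-genes scale this targets.
- Dense proximity matrices (O(n²) memory); adequate below ~5000 genes.
- The Bi-GRU is the computational bottleneck since it backpropagates
  through every token; long genomes should be truncated via `max_tokens`.
- The CVAE is transductive over node features (see above).
- Only the Bi-GRU recurrent encoder is implemented; LSTM/GRU variants and
  spaced dinucleotide descriptors (k > 0) are out of scope.
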