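# Methods

## Problem

Given a protein's amino-acid sequence, predict which of ten brain-development-
associated Gene Ontology terms annotate it (nine biological-process terms
such as *brain development*, GO:0007420, and one molecular-function term,
*olfactory receptor activity*, GO:0004984). Each protein may carry any
subset of terms, so the task is multi-label binary classification: the
target is a vector G ∈ {0,1}^10 whose positions are fixed by the ordered
term catalogue in `recgobd.catalogue.BRAIN_GO_TERMS`.

## Input representation: fused per-residue embeddings

Each sequence is encoded residue-by-residue by up to four strategies and the
resulting matrices are concatenated column-wise ("feature-level fusion")
after standardizing all of them to L rows:

| strategy  | width | source                                                       |
|-----------|------:|--------------------------------------------------------------|
| esm2      |  2560 | external protein language model, reached through an adapter  |
| protbert  |  1024 | external protein language model, reached through an adapter  |
| kmer2vec  |   100 | 3-mer distributional vectors, trainable in-package           |
| one_hot   |    20 | indicator of the residue identity (alphabetical order)       |

With all four strategies at the default L = 2000 the fused input is
(2000, 3704). Standardization truncates at the N-terminal side (the first L
residues are kept) and right-pads shorter sequences with zero rows; a
boolean validity mask travels with every standardized matrix and is consumed
by the attention layer. The k-mer block has L−k+1 = L−2 rows before
alignment; it is right-padded with k−1 zero rows so that row *i* of every
block describes residue *i*.

Design choices worth noting:

* **Language models are adapters, not dependencies.** The two large models
  are reached only through an adapter contract; requesting one without an
  installed backend raises an explicit error. `PLMStubEmbedder` satisfies
  the same contract with deterministic pseudo-embeddings (the elementwise
  product of a seeded residue vector and a seeded position vector), so every
  pipeline stage runs and is testable with no download or GPU. The stub
  carries residue identity and position, not biology; results obtained with
  it say nothing about the quality of real language-model embeddings.
* **k-mer vectors via PPMI + truncated SVD.** The 3-mer table (20³ = 8000
  entries, 100 dimensions) is learned from symmetric co-occurrence counts
  within a 5-token window, reweighted by positive pointwise mutual
  information and factorized by a seeded truncated SVD — the classical
  count-based equivalent of skip-gram training. K-mers absent from the
  corpus get small seeded random vectors so the table always covers the full
  vocabulary. Externally trained tables can be loaded from TSV instead.
* **Rare letters.** B/J/O/U/X/Z are mapped to one unknown symbol that
  one-hot-encodes as a zero row and knocks its k-mers out of the vocabulary
  (zero vectors). This preserves the stated 20/100-wide blocks exactly.
* **One-hot column order** is alphabetical (A first). The order is
  model-internal; no reported quantity depends on it.

## Network

The classifier maps the fused matrix X ∈ R^(L×D) to ten probabilities:

1. **Bidirectional LSTM.** A single-layer LSTM with H = 200 hidden units per
   direction (forget-gate bias initialized at 1) is run forward and
   backward; position t's output concatenates both states, giving a context
   matrix H ∈ R^(L×400). The hidden size is chosen so the encoder width
   equals the attention model width d_model = 400 below. Padded steps hold
   their state and are excluded downstream, so trailing padding is provably
   inert (property-tested).
2. **Category attention.** Queries come from a fixed, non-trainable 10 × 10
   identity matrix Q_input — one query row per GO term:

       Q = W_q Q_input + b_q,  K = W_k H + b_k,  V = W_v H + b_v
       X̂ = softmax(Q K^T / √d_k)  (softmax over sequence positions,
                                    padded keys excluded by a −10³⁰ offset)
       B = X̂ V

   with h = 4 heads of d_k = 100 dimensions; the heads are concatenated and
   projected by W_O (the projection can be disabled for ablation), yielding
   ten 400-dimensional per-term context vectors.
3. **Shared dense heads.** Each term's context vector passes through the
   same ReLU layer (400 → 128) and the same scalar linear read-out; weight
   sharing across the ten heads keeps the head parameter count at one
   dense layer. A sigmoid turns each logit into a probability.

The network, its backpropagation and the Adam optimizer are implemented in
NumPy (the time-step recursions of the LSTM are JIT-compiled with numba);
analytic gradients are verified against central finite differences to 1e−4
in the test suite, and the attention layer against a naive triple-loop
implementation to 1e−6.

## Losses

Both criteria operate on predicted probabilities p against binary targets y,
averaged over proteins and terms, with probabilities clipped at 1e−7 before
logarithms:

* binary cross-entropy: −y log p − (1−y) log(1−p);
* focal loss: −α(1−p)^γ log p on positives and −(1−α) p^γ log(1−p) on
  negatives. Defaults α = 0.25, γ = 2 (standard practice; configurable).
  At γ = 0 the focal loss reduces exactly to α-weighted cross-entropy,
  which is used as an identity test.

## Training protocol

Adam (learning rate 0.001 or 0.0005; optional step decay
lr·γ^⌊epoch/step⌋ with defaults step = 10, γ = 0.5), mini-batches of 32
(64 in the desk-scale experiment), early stopping on the validation loss
with patience 5 (strict improvement; a `min_delta` is exposed and defaults
to 0), and restoration of the best-epoch weights. Data are split 8:1:1
into train/validation/test by a seeded uniform shuffle — first ⌊0.8n⌋ ids
to train, next ⌊0.1n⌋ to validation, remainder to test; the split is not
stratified by label. Reported metrics average independent runs over several
seeds (five by default, three in the desk-scale experiment) on one fixed
split; one master seed fans out deterministically to parameter
initialization, batch shuffling and the internal validation split.

Two equivalences used for efficiency, both numerically neutral: batches are
padded to the batch's longest sequence (capped at L) instead of always to
L, which is exact because padding is masked; and batches are formed by
length-sorted bucketing within shuffled chunks, which only reorders the
stream of examples.

## Evaluation metrics

* **AUROC / AUPR**, macro-averaged over the ten terms (micro available by
  flag); terms lacking both classes in the evaluation set are excluded from
  the mean and reported as NaN rather than silently dropped. Per-term values
  use midrank tie handling (ROC) and step interpolation (PR).
* **Protein-centric Fmax.** For thresholds t ∈ {0, 0.01, …, 1}, protein i's
  predicted set P_i(t) is every term with score ≥ t. Precision pr_i(t) is
  averaged over the m(t) proteins with non-empty predictions; recall
  rc_i(t) over all n proteins, with rc_i defined as 0 for proteins whose
  truth set is empty (avoids 0/0). Fmax is the maximum over the grid of
  2·AvgPr·AvgRc/(AvgPr+AvgRc); thresholds with m(t) = 0 or a zero
  denominator contribute F = 0. The evaluation is flat over the ten terms —
  no ontology-graph propagation.

## Mutation gain/loss annotation

The variant pipeline consumes pre-translated pairs (reference protein,
post-mutation protein) together with verbatim genomic variant strings
(e.g. `C1645227CG`); translating genomic coordinates to protein changes is
out of scope. Both sequences are scored by a trained model, binarized at a
threshold τ (default 0.5, recorded in the report header), and every term
whose call flips is emitted as a gain (absent → present) or loss
(present → absent). A term can never yield both directions for one variant,
and identical predictions yield no record. Reports are TSV ordered by
chromosome (natural order) then variant, with BP/MF category abbreviations.

## Synthetic fixture

The generator plants one distinctive 6-residue motif per GO term into
otherwise uniform-random sequences: each sequence draws a primary label
uniformly and, with probability 0.3, one extra label; the motif of every
positive label is inserted at a random non-overlapping position; label bits
can then flip with a configurable noise rate (default 0). Motifs alternate
over disjoint letter pairs ("ACACAC", "DEDEDE", …), so neither motif
junctions nor deletion seams can spell a different motif, and a given motif
appears by chance in a 400-residue background with probability ≈ 6e−6.
Defaults: 2200 sequences of length 100–400.

With zero noise a substring scan recovers the labels perfectly, which
upper-bounds what the trained model can reach and certifies the fixture as
learnable. Mutation pairs delete one planted motif (expected loss) or
insert a new one (expected gain) with equal probability.

What the fixture does *not* emulate: real amino-acid background
frequencies, domain architecture, motif degeneracy, length/label
correlations, or informative language-model embeddings. Passing the
learnability test shows the architecture, losses, optimizer and metrics
interact correctly at realistic scale — not that the model attains any
particular accuracy on curated UniProt data.

## Desk-scale experiment sizes

The end-to-end experiment (tests and `scripts/acceptance.py`) uses the
package's desk-scale configuration: 2200 fixture sequences split 8:1:1,
fusion of one_hot (20) + kmer2vec (100) + a 32-wide stub adapter, encoder
hidden size 32 (d_model 64, 4 heads × 16), dense hidden 32, batch size 64,
BCE loss, learning rate 0.001, patience 5, at most 30 epochs, three seeds.
The full-size architecture (3704-wide fusion, 400-dimensional attention at
L = 2000) is exercised structurally and numerically but not trained, since
its value comes from real language-model embeddings.

## Numerical choices and degenerate inputs

* float32 parameters and activations for training; float64 supported and
  used in oracle/gradient tests.
* Masked softmax via an additive −10³⁰ pre-softmax offset; a batch row with
  an all-false mask is rejected, as are non-finite attention scores.
* Probability clipping at 1e−7 in both losses; the BCE logit gradient uses
  the exact (p − y)/N form.
* Glorot-uniform initialization throughout, seeded; forget-gate bias 1.
* Sequences shorter than k = 3 cannot be k-mer embedded; empty sequences
  are rejected at record construction.
* Checkpoints are plain `.npz` archives of named weight arrays plus the
  architecture as JSON; round-trips are bit-exact.

## Known limitations

* Single-layer recurrent encoder; depth is configurable in principle but
  one layer is what is implemented.
* The label-query projection interpretation (a per-head W_q applied to the
  identity label matrix) is one of two defensible readings of the
  architecture; the alternative (a single shared label map before per-head
  projections) differs only in parameterization capacity.
* No GPU path; CPU NumPy/numba only.
* No GO-hierarchy propagation, no UniProt/InterPro integration, no VCF or
  transcript handling.
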