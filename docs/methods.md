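# Methods

## Problem and model

`peppi` predicts, from sequence alone, (1) whether a peptide (≤ 50
residues) and a protein (> 50 residues) interact, and (2) which peptide
residues mediate the binding. Both tasks are learned jointly by one network:

1. **Featurization.** Each sequence becomes four parallel channels: three
   categorical code tracks — amino-acid type (21 codes: 20 canonical + `X`
   for anything else), a joint (amino acid × 3-class secondary structure)
   code, and a joint (polarity × hydropathy) physicochemical code — plus one
   dense numeric matrix: three per-residue intrinsic-disorder scores for
   both roles, and additionally a row-normalized 20-column PSSM for
   proteins. Sequences are zero-padded to a fixed length with a 0/1 mask;
   code 0 and all-zero numeric rows are reserved for padding.
2. **Channel embedding.** Each categorical track goes through its own
   learned embedding table (row 0 frozen at zero so padding contributes
   nothing); the numeric matrix goes through an affine map. The four
   d-dimensional outputs are concatenated into a per-residue vector
   u_i ∈ R^{4d}.
3. **Two extractors per chain.** (a) Three 1-D convolution layers
   ('same' padding, ReLU) produce per-position features H; a masked global
   max pool reduces H to one vector per chain. (b) Single-head scaled
   dot-product self-attention over the embedding output:
   g_i = Σ_j softmax_j(q_i·k_j/√d_k) v_j with q = W_q u, k = W_k u,
   v = W_v u; a masked mean pool reduces the attention output.
4. **Heads.** The four pooled vectors (peptide CNN, protein CNN, peptide
   attention, protein attention) are concatenated into a three-layer fully
   connected binary head (dropout after the first two layers, sigmoid
   output). The peptide's *pre-pooling* conv features feed a per-position
   single-layer residue head b_j = σ(W_pep·h_j + c).
5. **Losses.** Pair task: mean binary cross-entropy. Residue task: masked
   cross-entropy, normalized per sample by its own number of real residues
   M_i and then averaged over samples; samples without residue labels are
   fully masked and contribute zero. Total: loss_pair + λ·loss_pep.
   Both classification thresholds are 0.5, boundary inclusive.

Everything is NumPy. Gradients are hand-written reverse-mode passes for
each block, validated end-to-end against central finite differences (the
test suite requires < 1e-4 relative error on a micro-model). Training uses
RMSProp (decay 0.9, ε 1e-8); one integer seed drives initialization,
shuffling and dropout, so identical configs reproduce identical weights.

## Design choices where the architecture was open

- **Attention input** is the embedding-layer output U, not CNN features.
- **Attention masking**: padded keys get a large negative logit so their
  softmax weight underflows to exactly zero; attention rows at padded
  queries are zeroed. This makes every forward output invariant to the
  amount of trailing padding.
- **Attention pooling**: masked mean over unmasked positions.
- **Residue-head bias** c is a single shared scalar, not per-position: the
  head must score peptides of any length, and a per-position bias would
  break length generalization.
- **Residue head reads pre-pooling conv features** H; only the binary head
  sees the max-pooled summary. This is the only composition in which a
  global pooled array and per-position residue scores can coexist.
- **ReLU subgradient** at 0 is taken as 0. Padded conv inputs with
  zero-initialized biases sit exactly on this kink; gradient checks are
  therefore run at a jittered generic parameter point.
- **Probability clipping** at ε = 1e-7 before all logs.
- **Protein cap**: proteins are padded to a configurable length (default
  cap 800); longer proteins are tail-truncated (N-terminus kept) with a
  warning, since a fixed-length input requires some cap.
- **PSSM normalization** for externally supplied matrices is expected in
  [0,1]; the built-in stub emits per-row probability profiles. When raw
  log-odds are supplied, squashing through 1/(1+e^{-x}) is the documented
  convention.

Default architecture: embedding 16/channel, conv filters 64/64/128 with
kernels 7/5/3, d_k = 32, FC 256/128/1, dropout 0.2. A `TINY_ARCH` preset
(8/channel, 16/16/32 filters, d_k = 8, FC 64/32) is used for all synthetic
training runs in the tests and the reproduction script; it trains in
minutes on one CPU at the problem sizes below.

## Feature providers

Real pipelines derive PSSMs, secondary structure and disorder scores from
PSI-BLAST-, SSPro- and IUPred-class tools. The package consumes those
through a provider interface (sidecar text files listed in a manifest TSV)
and ships a deterministic stub provider — PSSM rows from normalized gamma
draws biased toward the observed residue, secondary structure from a sticky
3-state Markov chain, disorder from smoothed uniform noise, all seeded from
a hash of the sequence — so the full pipeline runs and tests without
external binaries. Stub features carry no biological signal; in synthetic
experiments all learnable signal lives in the sequence-derived categorical
channels.

## Homology-aware splitting

Pairwise similarity is normalized Smith–Waterman:
SW(a,b)/√(SW(a,a)·SW(b,b)) under BLOSUM62 with gap open 11 / extend 1
(standard protein local-alignment defaults). Entities are clustered by
single linkage (connected components of the ≥ t similarity graph;
deterministic cluster ids). Settings: `random` (seeded k-fold over pairs),
`novel_protein` / `novel_peptide` (clusters of that entity are balanced
into k groups by pair count; pairs follow their cluster), and `novel_pair`
(peptide × protein cluster groups in a 3×3 grid giving 9 folds whose test
blocks share no cluster of either kind with their train blocks; some pairs
are unused per fold by construction). `leakage_check` re-verifies the
disjointness contract on any plan. Default thresholds {0.3, 0.4, 0.5}.

Negative sampling draws exactly `ratio` negatives per positive, uniformly
without replacement from the peptide × protein combinations excluding all
existing pairs (5 per positive by default, matching the 1:5 convention for
interaction benchmarks).

## Synthetic data: what it emulates and what it does not

The generator plants complementary 4-mer motif pairs from a lookup
library. A fraction of the peptide pool (default 0.7) carries a peptide
k-mer at a recorded position, the same fraction of proteins carries a
partner k-mer, and a pair is positive exactly when both sides carry
complementary partners from the same library entry. Pools are small
relative to the pair count, so each sequence recurs across pairs with both
labels. The binding vector is 1 exactly at the planted peptide positions,
optionally flipped at a label-noise rate η < 0.5. Negative pairs are drawn
from pairings verified (by exhaustive k-mer scan) to contain no
complementary motif pair. Backgrounds are i.i.d. uniform over the 20
canonical letters. Optional homology families expand one ancestor per
family into point-mutated copies, giving the clustering something real to
recover.

Two calibration lessons are baked into the defaults. First, in an early
design motifs were planted only into the sequences of positive pairs, so
each peptide appeared in exactly one positive; a network of this capacity
then learned per-entity fingerprints (the deterministic stub features are
effectively sequence hashes) instead of the motif rule, and ranked
held-out positives of known entities *below* chance. Planting into the
pool rather than into pairs makes entity identity uninformative about the
label. Second, with a multi-entry library the label requires matching
*which* motif each side carries — a sum-of-products rule whose
optimization at desk scale is a seed lottery: runs that found the rule
generalized well, but many runs fit the training pairs another way and
stalled. The default library therefore holds a single complementary pair,
making the interaction rule a pure conjunction (peptide motif present AND
partner motif present); under a conjunction, any fit that respects the
product structure — including entity-level fits — generalizes to unseen
combinations of known entities, and training is stable across seeds.
Multi-entry libraries remain available (`MOTIF_LIBRARY_3`) for harder
benchmarks.

This emulates the *statistical* structure the model assumes — a localized,
complementary sequence determinant with per-residue labels and a 1:5 class
ratio — not binding chemistry: complementarity is symbolic, backgrounds
have no composition bias, and stub features are uninformative. Passing the
learnability tests therefore shows the architecture, losses, masking and
optimization can extract a plantable signal end-to-end; it says nothing
about accuracy on real interactomes.

Default generator conditions: 200 positives, ratio 5, peptide lengths
5–50, protein lengths 51–300, motif length 4, η = 0.

## Problem sizes and tolerances used in the checks

- Oracle-equivalence checks (attention, convolution, pooling, losses,
  Smith–Waterman, clustering, AUC) run on ≥ 50 random small instances at
  1e-6 absolute tolerance (Smith–Waterman scores are integers and must
  agree exactly).
- Gradient checks probe a few entries of every parameter array on a
  micro-model (embed 3, filters 4/4/5, d_k 3) with step 1e-5.
- Learnability runs use a dedicated preset (`LEARNABILITY_ARCH`: embed 8,
  conv 16/16/32, d_k 8, FC 32/16 — the narrow head limits the capacity
  available for memorizing pair-specific coincidences) trained on the
  200-positive dataset for 30 epochs with batch 32, RMSProp learning rate
  3e-3, λ = 1.0, dropout 0.2 (λ weights the auxiliary residue task up
  because its per-sample normalization makes its gradients small relative
  to the pair loss). Held-out checks use a seeded 80/20 random split over
  three seeds.
- Training arrays are float32; gradient checks use float64.

## Known limitations

- No learning-rate schedule, early stopping or ensembling.
- Attention is O(L²) in memory; proteins beyond a few thousand residues
  require truncation.
- The residue head is linear on conv features; binding patterns that are
  not locally encodable within the conv receptive field (13 residues) will
  not be captured.
- MCC on the residue task is pooled over all unmasked residues by default;
  a per-pair-averaged variant is available via a flag, and the two can
  differ substantially on imbalanced peptides.
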