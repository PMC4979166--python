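# Methods

## Model

The predictor treats RNA–protein partner prediction as binary
classification of sequence pairs. Its core assumption is that binding
propensity leaves a signature in sequence composition: over-represented
protein 3-mers (over a reduced 7-letter alphabet) and RNA 4-mers that
co-occur in interacting pairs. Everything downstream — the autoencoder, the
forests, the stacking layer — consumes only these composition vectors; no
structural or physicochemical features are used.

### Composition features

Feature vectors are normalized by the number of *valid* windows
(L − k + 1 minus windows containing a non-standard letter), so every vector
is a length-independent probability distribution over windowed composition.
Non-standard residues (X, B, Z, U, O, \*) and nucleotides (anything outside
A/C/G/U after T→U mapping) map to a sentinel and windows containing it are
skipped rather than rejected — PDB-derived sequences routinely contain X.
A sequence with zero valid windows yields an all-zero vector plus a warning.
Column order is fixed and documented: protein triad (g1,g2,g3) at flat
index (g1−1)·49 + (g2−1)·7 + (g3−1); RNA k-mer by base-4 expansion with
A=0 < C=1 < G=2 < U=3.

### Stacked denoising autoencoder

Per layer: encoder y = σ(Wx + b), decoder z = σ(Wᵀy + b′). The decoder
weight is the transpose of the encoder weight by construction, so the
tied-weight constraint cannot drift. Choices where the design was open:

- **Corruption**: masking noise (inputs independently zeroed with
  probability 0.5) during pretraining only; inference is noise-free. The
  same rate doubles as the dropout rate the training recipe calls for; no
  additional dropout is applied during fine-tuning.
- **Activations**: logistic sigmoid for both encoder and decoder; it keeps
  activations in [0,1], matching the input range of frequency features.
- **Optimizers**: per-layer pretraining minimizes reconstruction MSE with
  Adam (rate 1e-3); fine-tuning minimizes binary cross-entropy with SGD,
  momentum 0.9, rate 0.01. Epochs and batch size default to 100/100.
- **Output head**: a single sigmoid unit on the concatenation of the two
  sub-network top layers, trained jointly with all encoder weights. (A
  one-unit sigmoid head with cross-entropy is the 2-class softmax in
  disguise.)
- **Initialization**: Glorot-uniform ±√(6/(fan_in+fan_out)); biases zero.
- **Topology**: default mode "sep" trains two separate stacks
  (343→256-128-64 for protein, 256→256-128-64 for RNA); no parameter
  connects a protein input to an RNA hidden unit below the head, and the
  tests assert this structural independence. Mode "con" routes the 599-dim
  concatenation through a single 256-128-128 stack; "sep" is the default
  because mixing the two molecule types in shared hidden units lets their
  signals corrupt each other.
- Features are extracted from the **top hidden layer only** (not a
  concatenation across layers). Fine-tuning operates on deep copies, so
  the pre-fine-tuning (SDA) and post-fine-tuning (SDA-FT) feature sets are
  both available from one run.

All randomness (init, noise masks, batch shuffling) flows from a single
seed; two runs with the same seed produce bit-identical parameters.

### Stacked ensemble

Level-0: three random forests (default 100 trees, probability = fraction of
trees voting positive) over the raw 599-dim, SDA 128-dim and SDA-FT 128-dim
feature sets. Level-1: unpenalized logistic regression on the three base
probabilities. To avoid leakage the level-1 model is fitted on out-of-fold
level-0 predictions from an internal stratified 5-fold split (Wolpert-style
stacking); the base forests are then refit on all training data for
deployment. With equal weights and zero bias the combiner ranks samples
exactly like probability averaging, which the tests assert. The
classification threshold is 0.5 with ties called positive.

### Evaluation

Accuracy, sensitivity, specificity, precision and MCC follow the standard
confusion-table formulas; AUC is the trapezoidal ROC area (ties worth ½).
A metric with a zero denominator is reported as 0 and flagged, because
small stratified folds can produce degenerate prediction sets. The CV
harness uses stratified folds (class balance matters at these dataset
sizes), refits the *entire* pipeline — including autoencoder pretraining
and fine-tuning — inside each training fold, and canonicalizes pair order
before splitting so results are invariant to input file ordering.
Pretraining the autoencoder once on the full dataset would leak test-set
composition statistics into the folds; refitting per fold is deliberate
strictness.

### Structure-derived labeling

A protein chain and an RNA chain of the same complex are labeled
interactive when the minimum Euclidean distance over all atom pairs is
strictly less than the 5 Å cutoff; a pair at exactly 5 Å is
non-interactive. Sequences are taken from SEQRES records (the full
deposited chain), never from the coordinate subset. Only the first model of
multi-model entries is used; HETATM records are excluded from distance
computation by default (configurable); hydrogens count if present. Chains
are typed protein vs RNA by residue vocabulary with an 80 % dominance rule
for chains containing modified residues; hybrid chains are skipped with a
warning. Negative pairs are drawn uniformly without replacement from the
complement of the positive set; identity-based redundancy reduction is out
of scope — an externally produced keep-list can be applied instead.

### Network clustering

Predicted probabilities become edge weights of a bipartite graph (edges
below a threshold dropped, duplicate pairs keep the max weight). MCL runs
on the column-stochastic adjacency with unit self-loops, alternating
expansion (matrix squaring) and inflation (elementwise power 2.0 +
column renormalization, values < 1e−12 pruned) until the maximum change
falls below 1e−6 or 100 iterations. Clusters are read off attractor rows;
a node attracted by no attractor joins its strongest attractor's cluster,
with a singleton fallback. Node order is canonicalized, so output does not
depend on insertion order, and clusters never span connected components.

## Synthetic data

The generator emulates the k-mer co-occurrence premise directly: positives
receive a fixed protein motif (default `CRKCC`, hitting conjoint triads of
the rare Cys/Arg-Lys groups) and a fixed RNA motif (default `GCGC`)
overwritten at random positions (3 copies each by default, preserving
length); negatives are uniform-random background. Defaults: 400 pairs,
balanced, protein lengths 150–350, RNA lengths 100–300. What it does *not*
emulate: real base/residue composition biases, homology between sequences,
motif degeneracy, and unverified negatives mislabeled as non-interacting.
Passing the recovery tests therefore demonstrates that the pipeline can
learn co-occurring composition signals end to end, not that it reaches any
particular accuracy on deposited interaction data.

## Problem sizes and runtime choices

The end-to-end experiments (tests and the acceptance script) run the
400-pair planted-motif dataset through full 5-fold CV with 30 pretraining
and 30 fine-tuning epochs — on this dataset the reconstruction and
cross-entropy losses have plateaued well before epoch 30, so the shorter
schedule changes nothing but runtime; the 100/100 defaults remain for real
use. Unit tests use smaller architectures and epoch counts where only the
contract, not the learning outcome, is under test.

## Known limitations

- The numpy autoencoder is single-threaded and intended for datasets up to
  a few thousand pairs; there is no GPU path and no convolutional variant.
- Fine-tuning on very small datasets (tens of pairs) can leave the head
  near its initialization; the SDA-FT forest then adds little over SDA.
- mmCIF structures are not parsed in v1.
- MCL granularity is controlled only by the inflation exponent; no
  pruning-based scalability measures are implemented, so networks beyond a
  few thousand nodes will be slow.
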