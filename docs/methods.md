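# Methods

## Problem

Given drug SMILES strings, protein amino-acid sequences, and six boolean
association networks (drug–disease, drug–drug interaction, drug–target
interaction, drug–side-effect, target–disease, target–target
interaction), predict for each (drug, target) pair whether an interaction
exists. The model combines sequence-derived biological features with
heterogeneous-network representation learning and a random-forest
classifier; cross-validated AUC/AUPR under random and cold-start
(blind drug / blind protein / blind pair) protocols is the output.

## Sequence features

Proteins are tokenized into overlapping k-mers (default k = 3, the
worked-example convention), each k-mer one-hot encoded over the full
20^k canonical channel set so embeddings are corpus-independent; a
corpus-restricted vocabulary is available for memory economy, and
non-canonical residues (B, J, O, U, X, Z) map to a shared UNK channel by
default (configurable: `unk | error | drop`). Drug SMILES are tokenized
losslessly (bracket atoms and two-letter halogens are single tokens) over
a frozen 61-symbol vocabulary covering organic-subset atoms, bonds,
branches, ring digits and common bracket atoms. Maximum lengths L_D, L_T
default to the 95th-percentile corpus length rounded up to a multiple of
8; longer sequences truncate from the right, shorter ones pad with
all-zero columns behind an explicit mask.

The extractor maps each channel × length embedding to a fixed-length
vector: one *region-embedding* layer (N = 64 window-3 valid convolutions
over the one-hot channels, linear, scalar bias per kernel — a positional
bias would tie parameters to one sequence length and break padding
invariance), two *refinement* layers (full cross-channel window-3
convolutions with ReLU applied to the inputs; a depthwise reading of the
per-channel indexing is exposed as an option), then aggregation blocks
`X_{t+1} = P(X_t) + theta(P(X_t))` with stride-2 max pooling and a
residual theta realized as two window-1 convolutions with a rectifier
between them (dimension-preserving, matching the "linear weighting of the
pooled output" role; default 2 blocks), and finally a global max over the
valid positions, giving d_seq = N features per entity. Validity is
propagated strictly — an output position is valid only if its whole
receptive field is valid — so appending padding can never change the
output (a property test asserts this bit-exactly). The stack requires
`2·refine_layers + 2 + 2^blocks` valid tokens (10 at the defaults);
shorter sequences are a configuration error at build time.

## Similarity edges and the heterogeneous network

Four drug–drug scores: Jaccard similarity of neighbor sets in the
drug–disease, drug–drug-interaction and drug–side-effect networks
(empty-vs-empty neighbourhoods score 0 — no evidence of similarity), and
Tanimoto similarity of 167-bit MACCS structural-key fingerprints. Three
target–target scores: Jaccard in the target–disease and
target–target-interaction networks, and a sequence score built from
length and residue-composition differences: with sequence lengths S1, S2
and E the total absolute per-residue-type count difference, I = |S1−S2| +
2E and L = (S1+S2−I)/(S1+S2), clamped to [0, 1] because the raw value
goes negative for highly dissimilar compositions. (This count-based
reading of "differences in the length and types of amino acids" is
isolated in one function so alternative definitions can be swapped in;
no edit distance is involved.)

A similarity edge joins two same-kind entities when the **maximum** score
across sources **strictly exceeds** a threshold (default 0.5 for both
kinds, configurable per kind) and the pair has no known interaction.
The resulting graph G = (V, E, R) has drugs and targets as nodes — five
relations: drug–drug interaction, drug–drug similarity, drug–target
interaction, target–target interaction, target–target similarity.
Diseases and side effects feed the similarity computation only; they are
not nodes. Nodes are ordered drugs-first, lexicographic by id, for
determinism. Self-loops are added at propagation time (S̃ = I + S) and
degrees are taken from S̃ so the normalization is always invertible.

## Graph representation learning

Per layer, features propagate along each relation independently and sum:

* GCN: `X^{l+1} = Σ_r ReLU(A_r^{-1/2} S̃_r A_r^{-1/2} X^l W_r^l)`.
* GAT: K = 4 heads shared across relations; the logit for neighbor j of
  node i under relation r is `LeakyReLU(a_k^T [W_k x_i ‖ W_k x_j ‖ B_k r_ij])`,
  softmax-normalized over i's r-neighborhood. Because the edge-type term
  is constant within one relation's neighborhood it cancels in that
  softmax; it is kept as a parameter because the optional "universal"
  softmax (over all t ≠ i) makes it active. Heads are averaged and
  relations summed; neighborless nodes contribute zero (no NaNs).

The default stack is GCN → GAT → GCN (a graph attention layer between
two convolution layers); the alternative GAT → GAT → GCN order is one
config switch (`layer_order`). A fusion layer combats over-smoothing by
combining the first and third layer outputs — concatenation followed by a
learned window-1 convolution (a shared linear map) to dimension d = 128 —
and the result splits into drug rows X_D and target rows X_T.

Training is end-to-end and joint with the sequence CNNs: pair scores
u_ij = sigmoid(X_D(i)·X_T(j)) (the logistic squashing is needed because
raw inner products are unbounded; epsilon-clamped at 1e-7) are fit to the
0/1 interaction labels of a balanced sampled pair set — not all d_v × T_v
cells — with binary cross-entropy, adaptive-moment gradient descent
(lr 1e-3), up to 200 epochs with early stopping (patience 20) on a 10%
validation split of the balanced pairs. Initial weight scales are shrunk
by the relation count so the summed layer outputs keep initial pair
logits out of sigmoid saturation. All tensor math runs through a small
reverse-mode autodiff core written for this package (float32 by default;
a float64 mode is used where tests compare against high-precision
oracles), with every operator's gradient verified against central finite
differences.

## Classification and evaluation

The pair descriptor is the concatenation Z_ij = [X_D(i), X_T(j)]
(length 2d). Training folds are balanced to 1:1 by over-sampling
positives with replacement and under-sampling negatives without
replacement, meeting at the geometric mean of the class sizes; test folds
are never resampled. Negatives are drawn from unlabeled (0) cells — the
standard positive-unlabeled caveat applies. The classifier is a
500-tree random forest (sqrt(p) features per split, out-of-bag score on,
probability-averaged voting); a multilayer-perceptron head with a 0.5
score threshold is the `rf` ablation. The other ablations: `bio` (frozen
random node features instead of the sequence CNN), `het` (no graph
layers; a learned linear projection of the layer-0 features remains),
`sim` (similarity edges removed).

Metrics: TPR, FPR, precision, recall from confusion counts (undefined
ratios reported as NaN with a warning); ROC AUC by trapezoidal
integration (equal to the Mann–Whitney statistic with midrank ties) and
AUPR by step-wise precision–recall integration. Splits: stratified
random k-fold over pairs (constant fold-wise positive rate, needed for
stable AUPR), or grouped k-fold cold-start splits — blind-drug /
blind-protein partition the entity ids; blind-pair partitions both and
*discards* mixed pairs, the strictest reading of "no overlap". Every
plan is audited for id leakage. Per fold, the test interactions are
removed from the graph's drug–target relation before training. Repeated
CV averaging is available (`--runs`), default off at desk scale.

## Synthetic data

The generator emulates the full input bundle with a planted
latent-community model: drugs, targets, diseases and side effects are
assigned to communities (default 3); every association matrix draws
edges Bernoulli(p_in = 0.25) within a community and Bernoulli(p_out =
0.02) across, so network-Jaccard similarity is community-informative.
SMILES come from a curated library of 24 valid drug-like scaffolds × 16
substituents, scaffolds partitioned by community (fingerprint similarity
is then community-informative, and every string parses without a
generative chemistry model); proteins draw 60–140 residues with a
community-biased composition (6 residue types enriched 3×), making the
composition similarity informative. Default desk-scale size is 60 drugs,
90 targets, 150 diseases, 120 side effects — small enough that the full
5-fold pipeline runs in about two minutes per seed on one CPU.
A matched null (p_in = p_out at the midpoint) plants no signal.

**What the synthetic benchmark does and does not show.** Real DTI data
have heavy-tailed degree distributions, correlated assay biases, and
molecular series far richer than a scaffold library; passing here shows
the machinery recovers planted block structure, not that it matches
benchmark accuracy on curated databases. One property deserves emphasis:
under the planted model, drug–target cells are independent Bernoulli
*given* community membership, so the best possible held-out score is the
community indicator. At the default conditions this puts an information
ceiling of ≈ 0.79 on held-out AUC (an oracle scoring each pair by the
true hidden community indicator measures ≈ 0.794, averaged over seeds
and folds — the test suite recomputes this); the pipeline's
0.73–0.78 (seed-dependent) should be read against that ceiling, not
against 1.0.

## Numerical and design notes

* Degenerate inputs: empty neighbourhoods (Jaccard), all-zero
  fingerprints (Tanimoto) and neighborless attention rows all score 0 by
  convention; single-class folds raise rather than emit NaN metrics.
* The protein one-hot space is exactly 20^k channels; the UNK channel is
  appended only when the corpus actually contains non-canonical residues.
* Strict inequality for the similarity-edge threshold, so threshold 1.0
  yields no edges.
* All randomness funnels through per-run integer seeds (fold seeds are
  derived arithmetically); repeated runs with one seed are bit-identical.
* Problem sizes in the shipped tests and the acceptance script (2–5
  folds, 1–3 seeds, the 60×90 default bundle) are the package's
  desk-scale reference conditions; larger instances only need the same
  config objects with larger counts.
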