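# hetdti

Drug–target interaction (DTI) prediction from biological sequence
features and heterogeneous-network representation learning.

Experimentally confirming which drugs bind which protein targets is slow
and expensive, so computational screening of the drug × target matrix is
a standard step in drug discovery and repurposing. `hetdti` implements a
hybrid pipeline for researchers who have (i) drug SMILES strings, (ii)
protein sequences, and (iii) a handful of boolean association networks
(drug–disease, drug–drug, drug–target, drug–side-effect, target–disease,
target–target), and want ranked interaction probabilities for unlabeled
pairs together with honest cross-validated and cold-start performance
estimates.

## The model

1. **Sequence features.** Protein sequences are one-hot encoded as
   overlapping k-mers (k = 3, channel space 20^k); SMILES are tokenized
   losslessly over a 61-symbol vocabulary. A convolutional stack — one
   region-embedding layer (64 window-3 kernels), two cross-channel
   refinement layers, and residual max-pooling aggregation blocks
   `X_{t+1} = P(X_t) + θ(P(X_t))` — maps each sequence to a fixed-length
   feature vector.
2. **Heterogeneous network.** Drugs and targets are nodes; five edge
   relations: drug–drug interaction, drug–drug similarity, drug–target
   interaction, target–target interaction, target–target similarity.
   Similarity edges are inserted where any of the multi-source scores
   (network Jaccard, MACCS/Tanimoto fingerprints for drugs,
   length/composition similarity for proteins) strictly exceeds a
   threshold and no interaction is known.
3. **Graph encoder.** A relational GCN → GAT → GCN stack,
   `X^{l+1} = Σ_r σ(A_r^{-1/2} S̃_r A_r^{-1/2} X^l W_r^l)` for
   convolution layers and per-relation multi-head softmax attention for
   the middle layer, with a fusion layer combining the first and third
   layer outputs into final embeddings X_D ∈ R^{d_v×d}, X_T ∈ R^{T_v×d}.
   The encoder and the sequence CNNs are trained jointly with binary
   cross-entropy on the preference matrix U = X_D X_Tᵀ (logistic-squashed),
   on a balanced sample of labeled pairs.
4. **Classifier.** Pair descriptors Z_ij = [X_D(i), X_T(j)] feed a
   500-tree random forest; evaluation reports ROC AUC and AUPR under
   stratified 5-fold CV and three cold-start protocols (blind drug,
   blind protein, blind pair).

A seeded synthetic-data module generates complete input bundles with
planted community structure, so the whole pipeline is testable without
any external download. Every neural component runs on a small
reverse-mode autodiff core included in the package — no deep-learning
framework required.

## Worked example

```bash
hetdti simulate --out data/ --seed 1
hetdti evaluate --data data/ --out report/ --seed 1
```

which prints, after about two minutes on one CPU:

```
wrote bundle (60 drugs, 90 targets) to data/
random: mean AUC 0.757, mean AUPR 0.213
```

Those numbers are 5-fold cross-validated on a synthetic bundle of 60
drugs × 90 targets with three planted communities (within-community
interaction probability 0.25, background 0.02). Held-out AUC 0.76 means
the learned embeddings rank true held-out interactions above unlabeled
pairs far better than chance (0.5) — and close to this benchmark's
information ceiling of ≈ 0.79, the score of an oracle that knows the
true hidden communities (see `docs/methods.md`). AUPR is reported
against a ~10% test-fold positive rate, so 0.21 is roughly two-fold
enrichment over random screening.

The same driver exposes the cold-start protocols and ablation switches:

```bash
hetdti evaluate --data data/ --out report_blind/ --mode blind_drug --seed 1
hetdti evaluate --data data/ --out report_mlp/ --ablate rf --seed 1
```

Library use mirrors the CLI:

```python
from hetdti import PipelineConfig, cross_validate
from hetdti.synthetic import SyntheticConfig, generate_dataset

bundle = generate_dataset(SyntheticConfig(seed=1))
report = cross_validate(bundle, PipelineConfig(), seed=1)
print(report.mean_auc, report.mean_aupr)
```

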