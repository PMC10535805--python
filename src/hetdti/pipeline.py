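"""End-to-end orchestration: featurize -> network -> train -> classify.

One :class:`PipelineConfig` (schema-validated, unknown keys rejected)
carries every hyperparameter.  The four ablation switches mirror the
framework's components: ``bio`` replaces the sequence CNN features with a
frozen random matrix, ``het`` removes the graph layers (a learned linear
projection remains), ``sim`` drops the similarity edges from the network,
and ``rf`` swaps the random forest for a multilayer-perceptron head.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import cnn as cnn_mod
from . import graph as graph_mod
from .evaluation import CvReport, SplitMode, make_splits, pr_auc, roc_auc
from .hetnet import HeterogeneousNetwork, assemble_network
from .prediction import balance_samples, descriptor_matrix, predict, train_mlp, train_rf
from .sequences import (
    build_kmer_vocabulary,
    build_smiles_vocabulary,
    default_max_length,
    encode_drug,
    encode_protein,
)
from .similarity import (
    add_similarity_edges,
    fingerprint_similarity,
    jaccard_network_similarity,
    sequence_similarity_matrix,
)
from .synthetic import Bundle


class PipelineConfig(BaseModel):
    """All knobs of the pipeline; defaults are the reference conditions."""

    model_config = ConfigDict(extra="forbid")

    # sequence encoding
    kmer_k: int = 3
    protein_vocab_mode: Literal["full", "corpus"] = "full"
    unknown_token_policy: Literal["unk", "error", "drop"] = "unk"
    max_drug_len: int | None = None  # None: 95th percentile, rounded up to 8
    max_protein_len: int | None = None

    # CNN extractor
    cnn_kernels: int = 64
    cnn_refine_layers: int = 2
    cnn_blocks: int = 2

    # similarity / network
    similarity_threshold_drug: float = 0.5
    similarity_threshold_target: float = 0.5

    # graph encoder
    embed_dim: int = 128
    attention_heads: int = 4
    layer_order: tuple[str, str, str] = ("gcn", "gat", "gcn")
    universal_softmax: bool = False
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1

    # classifier
    rf_trees: int = 500
    balance_ratio: float = 1.0

    # evaluation
    split_mode: SplitMode = "random"
    n_folds: int = 5

    # ablation switches: subset of {"bio", "het", "sim", "rf"}
    ablate: tuple[str, ...] = ()

    def model_post_init(self, _ctx) -> None:
        bad = set(self.ablate) - {"bio", "het", "sim", "rf"}
        if bad:
            raise ValueError(f"unknown ablation switches {sorted(bad)}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


class Featurized:
    """Index-encoded sequences for the batched CNN path."""

    def __init__(self, bundle: Bundle, cfg: PipelineConfig):
        kvocab = build_kmer_vocabulary(
            bundle.proteins, k=cfg.kmer_k, mode=cfg.protein_vocab_mode,
            residue_policy=cfg.unknown_token_policy,
        )
        svocab = build_smiles_vocabulary()
        L_D = cfg.max_drug_len or default_max_length([len(d) for d in bundle.drugs])
        L_T = cfg.max_protein_len or default_max_length(
            [len(p) - cfg.kmer_k + 1 for p in bundle.proteins]
        )
        d_emb = [encode_drug(d, svocab, L_D, cfg.unknown_token_policy) for d in bundle.drugs]
        p_emb = [encode_protein(p, kvocab, L_T, cfg.unknown_token_policy) for p in bundle.proteins]
        self.kmer_vocab = kvocab
        self.smiles_vocab = svocab
        self.drug_tokens = np.stack([e.indices for e in d_emb])
        self.drug_valid = np.array([e.n_valid for e in d_emb])
        self.protein_tokens = np.stack([e.indices for e in p_emb])
        self.protein_valid = np.array([e.n_valid for e in p_emb])


class SequenceFeatureSource(graph_mod.NodeFeatureSource):
    """Layer-0 node features from the trainable sequence CNNs.

    Drugs and proteins get separate extractors (different vocabularies)
    with a shared output dimension; rows are stacked drugs-first to match
    the network's node order.
    """

    def __init__(self, feats: Featurized, cfg: PipelineConfig, rng: np.random.Generator):
        ccfg = cnn_mod.CnnConfig(
            n_kernels=cfg.cnn_kernels,
            n_refine_layers=cfg.cnn_refine_layers,
            n_blocks=cfg.cnn_blocks,
        )
        self.drug_params = cnn_mod.init_cnn_params(feats.smiles_vocab.size, ccfg, rng)
        self.protein_params = cnn_mod.init_cnn_params(feats.kmer_vocab.size, ccfg, rng)
        self.feats = feats
        self.n_drugs = feats.drug_tokens.shape[0]
        self.dim = ccfg.n_kernels

    def forward(self):
        xd = cnn_mod.forward_batch(
            self.feats.drug_tokens, self.feats.drug_valid, self.drug_params
        )
        xp = cnn_mod.forward_batch(
            self.feats.protein_tokens, self.feats.protein_valid, self.protein_params
        )
        from . import autodiff as ad

        return ad.concat([xd, xp], axis=0)

    def tensors(self):
        return self.drug_params.tensors() + self.protein_params.tensors()


class RandomFeatureSource(graph_mod.NodeFeatureSource):
    """Frozen random layer-0 features (the sequence-ablation variant)."""

    def __init__(self, n_drugs: int, n_targets: int, dim: int, rng: np.random.Generator):
        from .autodiff import Tensor

        self.X = Tensor(rng.normal(0, 1, (n_drugs + n_targets, dim)))
        self.n_drugs = n_drugs
        self.dim = dim

    def forward(self):
        return self.X

    def tensors(self):
        return []


def similarity_edge_sets(bundle: Bundle, cfg: PipelineConfig):
    """Thresholded drug-drug and target-target similarity edges.

    Drugs: three network-Jaccard scores + fingerprint Tanimoto.
    Targets: two network-Jaccard scores + sequence composition similarity.
    """
    drug_scores = [
        jaccard_network_similarity(bundle.drug_disease),
        jaccard_network_similarity(bundle.drug_drug, source="network-interaction"),
        jaccard_network_similarity(bundle.drug_side_effect),
        fingerprint_similarity(bundle.drugs),
    ]
    target_scores = [
        jaccard_network_similarity(bundle.target_disease),
        jaccard_network_similarity(bundle.target_target, source="network-interaction"),
        sequence_similarity_matrix(bundle.proteins),
    ]
    drug_edges = add_similarity_edges(
        drug_scores, cfg.similarity_threshold_drug, bundle.drug_drug
    )
    target_edges = add_similarity_edges(
        target_scores, cfg.similarity_threshold_target, bundle.target_target
    )
    return drug_edges, target_edges


def build_network(
    bundle: Bundle,
    cfg: PipelineConfig,
    dti_values: np.ndarray | None = None,
    sim_edges: tuple[list, list] | None = None,
) -> HeterogeneousNetwork:
    """Assemble G; ``dti_values`` overrides the drug-target block (used to
    hide test-fold interactions during training)."""
    from dataclasses import replace as dc_replace

    dti = bundle.drug_target
    if dti_values is not None:
        dti = dc_replace(dti, values=np.asarray(dti_values, dtype=bool))
    if "sim" in cfg.ablate:
        drug_edges, target_edges = [], []
    else:
        if sim_edges is None:
            sim_edges = similarity_edge_sets(bundle, cfg)
        drug_edges, target_edges = sim_edges
    return assemble_network(
        bundle.drug_ids, bundle.target_ids,
        bundle.drug_drug, dti, bundle.target_target,
        drug_edges, target_edges,
    )


def build_model(
    feats: Featurized,
    network: HeterogeneousNetwork,
    cfg: PipelineConfig,
    seed: int,
) -> graph_mod.JointRepresentationModel:
    rng = np.random.default_rng(seed)
    if "bio" in cfg.ablate:
        source: graph_mod.NodeFeatureSource = RandomFeatureSource(
            network.n_drugs, network.n_targets, cfg.cnn_kernels, rng
        )
    else:
        source = SequenceFeatureSource(feats, cfg, rng)
    if "het" in cfg.ablate:
        from .autodiff import Tensor

        proj = graph_mod.FusionParams(
            W=Tensor(rng.normal(0, np.sqrt(1.0 / source.dim), (source.dim, cfg.embed_dim)),
                     requires_grad=True),
            b=Tensor(np.zeros(cfg.embed_dim), requires_grad=True),
        )
        return graph_mod.JointRepresentationModel(source, None, None, proj)
    structure = graph_mod.GraphStructure(network)
    enc_cfg = graph_mod.EncoderConfig(
        d=cfg.embed_dim,
        n_heads=cfg.attention_heads,
        layer_order=tuple(cfg.layer_order),
        universal_softmax=cfg.universal_softmax,
    )
    encoder = graph_mod.init_encoder_params(source.dim, enc_cfg, rng)
    return graph_mod.JointRepresentationModel(source, structure, encoder)


def run_fold(
    bundle: Bundle,
    feats: Featurized,
    cfg: PipelineConfig,
    pairs: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    sim_edges: tuple[list, list] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on the training side of one fold, score its test pairs.

    Test-fold interactions are removed from the graph's drug-target
    relation; resampling touches the training side only.
    """
    dti_train = bundle.drug_target.values.copy()
    test_pos = test_idx[labels[test_idx] == 1]
    dti_train[pairs[test_pos, 0], pairs[test_pos, 1]] = False

    network = build_network(bundle, cfg, dti_train, sim_edges)
    model = build_model(feats, network, cfg, seed)

    tr_pairs, tr_labels = pairs[train_idx], labels[train_idx]
    bal_pairs, bal_labels = balance_samples(tr_pairs, tr_labels, seed, cfg.balance_ratio)
    rng = np.random.default_rng(seed + 1)
    n_val = max(2, int(len(bal_pairs) * cfg.val_fraction))
    perm = rng.permutation(len(bal_pairs))
    val_sel, tr_sel = perm[:n_val], perm[n_val:]
    graph_mod.train_encoder(
        model,
        bal_pairs[tr_sel], bal_labels[tr_sel],
        bal_pairs[val_sel], bal_labels[val_sel],
        lr=cfg.learning_rate, epochs=cfg.epochs, patience=cfg.patience,
    )
    X_D, X_T = model.embeddings()

    Z_train = descriptor_matrix(X_D, X_T, bal_pairs)
    if "rf" in cfg.ablate:
        clf = train_mlp(Z_train, bal_labels, seed)
    else:
        clf = train_rf(Z_train, bal_labels, seed, n_trees=cfg.rf_trees)
    Z_test = descriptor_matrix(X_D, X_T, pairs[test_idx])
    scores, _hard = predict(clf, Z_test)
    return scores, labels[test_idx]


def cross_validate(
    bundle: Bundle,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    return_scores: bool = False,
):
    """k-fold cross-validated pipeline under the configured split mode.

    With ``return_scores`` the per-fold (scores, labels) arrays are
    returned alongside the report, e.g. for ROC/PR curve plotting.
    """
    cfg = cfg or PipelineConfig()
    feats = Featurized(bundle, cfg)
    pairs, labels = bundle.labeled_pairs()
    plan = make_splits(pairs, labels, mode=cfg.split_mode, k=cfg.n_folds, seed=seed)
    sim_edges = None if "sim" in cfg.ablate else similarity_edge_sets(bundle, cfg)
    fold_auc, fold_aupr, fold_scores = [], [], []
    for f, (tr, te) in enumerate(plan.folds):
        scores, y = run_fold(
            bundle, feats, cfg, pairs, labels, tr, te, seed + 37 * f, sim_edges
        )
        fold_auc.append(roc_auc(scores, y))
        fold_aupr.append(pr_auc(scores, y))
        fold_scores.append((scores, y))
    report = CvReport(
        mode=cfg.split_mode, fold_auc=fold_auc, fold_aupr=fold_aupr, seed=seed,
        extra={"config_hash": cfg.config_hash()},
    )
    return (report, fold_scores) if return_scores else report


def save_model_params(model, directory) -> None:
    """Checkpoint: parameter blob (npz) + JSON manifest of shapes."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = model.parameters()
    np.savez_compressed(
        directory / "params.npz", **{f"p{i}": p.data for i, p in enumerate(params)}
    )
    (directory / "params_manifest.json").write_text(
        json.dumps({"n_params": len(params),
                    "shapes": [list(p.shape) for p in params]}, indent=1)
    )


def load_model_params(model, directory) -> None:
    """Restore a checkpoint into a structurally identical model."""
    from pathlib import Path

    directory = Path(directory)
    blob = np.load(directory / "params.npz")
    manifest = json.loads((directory / "params_manifest.json").read_text())
    params = model.parameters()
    if len(params) != manifest["n_params"]:
        raise ValueError("checkpoint does not match the model architecture")
    for i, p in enumerate(params):
        arr = blob[f"p{i}"]
        if list(arr.shape) != list(p.shape):
            raise ValueError(f"parameter {i}: shape {arr.shape} != {p.shape}")
        p.data = arr.astype(p.data.dtype)
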