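"""Pair descriptors, class balancing, and the random-forest classifier.

A drug-target pair (i, j) is described by the concatenation
Z_ij = [X_D(i), X_T(j)] of the learned drug and target representations
(length 2d).  Known interactions are vastly outnumbered by unlabeled
pairs, so the training side is balanced by over-sampling positives with
replacement and under-sampling negatives without replacement; test folds
are never resampled.  The classifier is a bagged decision-tree ensemble
scored by averaged tree probabilities, with a multilayer-perceptron head
available as an ablation variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier


@dataclass
class PairDescriptor:
    drug_id: str
    target_id: str
    z: np.ndarray  # length 2d
    label: int | None = None


def fuse_descriptor(
    X_D: np.ndarray,
    X_T: np.ndarray,
    drug_ids: tuple[str, ...],
    target_ids: tuple[str, ...],
    pairs: list[tuple[str, str]] | np.ndarray,
    labels: np.ndarray | None = None,
) -> list[PairDescriptor]:
    """Z_ij = [X_D(i), X_T(j)] for each requested pair, drug part first."""
    dpos = {x: i for i, x in enumerate(drug_ids)}
    tpos = {x: i for i, x in enumerate(target_ids)}
    out = []
    for k, (d, t) in enumerate(pairs):
        if d not in dpos:
            raise KeyError(f"unknown drug id {d!r}")
        if t not in tpos:
            raise KeyError(f"unknown target id {t!r}")
        out.append(
            PairDescriptor(
                d, t,
                np.concatenate([X_D[dpos[d]], X_T[tpos[t]]]),
                None if labels is None else int(labels[k]),
            )
        )
    return out


def descriptor_matrix(
    X_D: np.ndarray, X_T: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Vectorized descriptor rows for integer (drug_idx, target_idx) pairs."""
    return np.hstack([X_D[pairs[:, 0]], X_T[pairs[:, 1]]])


def balance_samples(
    pairs: np.ndarray,
    labels: np.ndarray,
    seed: int,
    ratio: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Over-sample positives (with replacement) and under-sample negatives
    (without) until #pos : #neg = ``ratio``.

    The final per-class counts meet in the middle: positives are raised to
    and negatives lowered to n = round(sqrt(n_pos * n_neg / ratio) * ...) —
    concretely the geometric compromise n_pos' = n_neg' * ratio with
    n_neg' = round(sqrt(n_pos * n_neg)).  Already-balanced input at ratio
    1 is returned with unchanged class sizes.  Fully seeded.
    """
    pairs = np.asarray(pairs)
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present before balancing")
    rng = np.random.default_rng(seed)
    n_neg = int(round(np.sqrt(len(pos) * len(neg))))
    n_neg = min(n_neg, len(neg))
    n_pos = max(1, int(round(n_neg * ratio)))
    if ratio == 1.0 and len(pos) == len(neg):
        n_pos = n_neg = len(pos)
    pos_take = pos if n_pos == len(pos) else rng.choice(pos, size=n_pos, replace=True)
    neg_take = neg if n_neg == len(neg) else rng.choice(neg, size=n_neg, replace=False)
    keep = np.concatenate([pos_take, neg_take])
    rng.shuffle(keep)
    return pairs[keep], labels[keep]


def train_rf(
    descriptors: np.ndarray,
    labels: np.ndarray,
    seed: int,
    n_trees: int = 500,
):
    """Bagged decision-tree ensemble (sqrt(p) features per split, OOB on)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(descriptors, labels)
    return clf


def train_mlp(
    descriptors: np.ndarray,
    labels: np.ndarray,
    seed: int,
    hidden: tuple[int, ...] = (128,),
):
    """Multilayer-perceptron head (the end-to-end ablation variant)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = MLPClassifier(
        hidden_layer_sizes=hidden, max_iter=300, random_state=seed
    )
    clf.fit(descriptors, labels)
    return clf


def predict(
    classifier, descriptors: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Interaction probabilities and hard labels at ``threshold``."""
    descriptors = np.asarray(descriptors)
    if descriptors.size == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    if descriptors.shape[1] != classifier.n_features_in_:
        raise ValueError(
            f"descriptor length {descriptors.shape[1]} != trained length "
            f"{classifier.n_features_in_}"
        )
    proba = classifier.predict_proba(descriptors)
    pos_col = list(classifier.classes_).index(1)
    scores = proba[:, pos_col]
    return scores, (scores >= threshold).astype(int)
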