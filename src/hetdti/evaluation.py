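"""Evaluation: confusion metrics, ROC/PR AUC, CV and cold-start splits.

Four split protocols are supported: stratified random k-fold over pairs,
and three cold-start protocols in which test drugs (blind drug), test
proteins (blind protein) or both ends (blind pair) never occur in
training.  Blind-pair folds partition drugs and proteins independently
and discard pairs with mixed membership, the strictest reading of "no
overlap".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

SplitMode = Literal["random", "blind_drug", "blind_protein", "blind_pair"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """TPR, FPR, precision and recall; undefined ratios are NaN + warning."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    return {
        "tpr": ratio(c.tp, c.tp + c.fn, "TPR"),
        "fpr": ratio(c.fp, c.tn + c.fp, "FPR"),
        "precision": ratio(c.tp, c.tp + c.fp, "precision"),
        "recall": ratio(c.tp, c.tp + c.fn, "recall"),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; equals the Mann-Whitney
    concordance statistic with midrank tie handling)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR AUC needs both classes present")
    return float(average_precision_score(labels, scores))


def roc_curve_points(scores, labels):
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return (fpr, tpr), (rec, prec)


@dataclass
class SplitPlan:
    """Disjoint, covering train/test fold assignment over labeled pairs."""

    mode: SplitMode
    k: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train idx, test idx) per fold

    def audit(self, pairs: np.ndarray) -> None:
        """Leakage audit: verify the mode-specific id disjointness."""
        for f, (tr, te) in enumerate(self.folds):
            if np.intersect1d(tr, te).size:
                raise AssertionError(f"fold {f}: train/test pair overlap")
            if self.mode in ("blind_drug", "blind_pair"):
                if np.intersect1d(pairs[tr, 0], pairs[te, 0]).size:
                    raise AssertionError(f"fold {f}: drug leakage")
            if self.mode in ("blind_protein", "blind_pair"):
                if np.intersect1d(pairs[tr, 1], pairs[te, 1]).size:
                    raise AssertionError(f"fold {f}: protein leakage")


def make_splits(
    pairs: np.ndarray,
    labels: np.ndarray,
    mode: SplitMode = "random",
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """k-fold split plan over integer (drug_idx, target_idx) pairs.

    random: stratified k-fold over pairs (fold-wise positive rate
    constant).  blind_drug / blind_protein: the entity ids are partitioned
    into k groups; a fold's test set is every pair whose entity falls in
    the held-out group.  blind_pair: drugs AND proteins are partitioned;
    test pairs have both ends held out and mixed pairs are discarded from
    both sides of that fold.
    """
    pairs = np.asarray(pairs)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if mode == "random":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(pairs, labels)]
    elif mode in ("blind_drug", "blind_protein"):
        col = 0 if mode == "blind_drug" else 1
        ids = np.unique(pairs[:, col])
        if len(ids) < k:
            raise ValueError(f"{mode}: only {len(ids)} entities for {k} folds")
        groups = _partition(ids, k, rng)
        for g in groups:
            te = np.flatnonzero(np.isin(pairs[:, col], g))
            tr = np.flatnonzero(~np.isin(pairs[:, col], g))
            folds.append((tr, te))
    elif mode == "blind_pair":
        d_ids = np.unique(pairs[:, 0])
        t_ids = np.unique(pairs[:, 1])
        if len(d_ids) < k or len(t_ids) < k:
            raise ValueError(f"blind_pair: fewer than {k} drugs or proteins")
        d_groups = _partition(d_ids, k, rng)
        t_groups = _partition(t_ids, k, rng)
        for dg, tg in zip(d_groups, t_groups):
            d_held = np.isin(pairs[:, 0], dg)
            t_held = np.isin(pairs[:, 1], tg)
            te = np.flatnonzero(d_held & t_held)
            tr = np.flatnonzero(~d_held & ~t_held)  # mixed pairs discarded
            folds.append((tr, te))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    plan = SplitPlan(mode, k, seed, folds)
    plan.audit(pairs)
    return plan


def _partition(ids: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    ids = rng.permutation(ids)
    return [ids[i::k] for i in range(k)]


@dataclass
class CvReport:
    mode: SplitMode
    fold_auc: list[float]
    fold_aupr: list[float]
    seed: int
    extra: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "fold_auc": self.fold_auc,
                "fold_aupr": self.fold_aupr,
                "mean_auc": self.mean_auc,
                "mean_aupr": self.mean_aupr,
                **self.extra,
            },
            indent=1,
        ))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fold,auc,aupr\n")
            for i, (a, p) in enumerate(zip(self.fold_auc, self.fold_aupr)):
                fh.write(f"{i},{a:.6f},{p:.6f}\n")
            fh.write(f"mean,{self.mean_auc:.6f},{self.mean_aupr:.6f}\n")


def run_cv(dataset, config=None, seed: int = 0, n_runs: int = 1) -> CvReport:
    """Full cross-validated pipeline: per fold, train the joint encoder and
    the random-forest head on the training side only (the fold's test
    interactions are removed from the graph) and score the test pairs.

    ``n_runs`` > 1 averages repeated CV runs over derived seeds.
    """
    from .pipeline import PipelineConfig, cross_validate  # deferred: avoids cycle

    config = config or PipelineConfig()
    if n_runs == 1:
        return cross_validate(dataset, config, seed)
    reports = [cross_validate(dataset, config, seed + 1000 * r) for r in range(n_runs)]
    return CvReport(
        mode=config.split_mode,
        fold_auc=[r.mean_auc for r in reports],
        fold_aupr=[r.mean_aupr for r in reports],
        seed=seed,
        extra={"n_runs": n_runs},
    )
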