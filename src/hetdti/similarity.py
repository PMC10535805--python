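"""Drug-drug and target-target similarity scores and thresholded edges.

Four scores feed the drug side: Jaccard similarity of neighbor sets in the
drug-disease, drug-drug-interaction and drug-side-effect association
networks, plus Tanimoto similarity of 167-bit MACCS structural-key
fingerprints.  Three feed the target side: Jaccard similarity in the
target-disease and target-target-interaction networks, plus a sequence
similarity built from length and per-residue composition differences.
A similarity edge is inserted between two entities when any score exceeds
a threshold and the pair has no known interaction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

from .sequences import AMINO_ACIDS, DrugSmiles, ProteinSequence

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

MACCS_BITS = 167  # 166 catalogued substructures + 1 reserved bit


@dataclass
class AssociationMatrix:
    """Boolean association matrix between two entity kinds."""

    row_kind: str
    col_kind: str
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError(
                    f"{self.row_kind}-{self.col_kind} matrix has non-boolean "
                    f"entries {uniq[~np.isin(uniq, [0, 1])][:5]}"
                )
            self.values = self.values.astype(bool)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")


@dataclass
class Fingerprint:
    """167-bit MACCS structural-key vector of one drug."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(bool)
        if self.bits.shape != (MACCS_BITS,):
            raise ValueError(
                f"fingerprint for {self.drug_id!r} has length "
                f"{self.bits.shape}, expected ({MACCS_BITS},)"
            )

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with a source tag."""

    kind: str
    ids: tuple[str, ...]
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("similarity matrix must be square over the id list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, a in enumerate(self.ids):
                for j in range(i + 1, len(self.ids)):
                    if self.values[i, j] > 0:
                        fh.write(
                            f"{a}\t{self.ids[j]}\t{self.values[i, j]:.6g}"
                            f"\t{self.source}\n"
                        )


def jaccard_network_similarity(
    A: AssociationMatrix, source: str | None = None
) -> SimilarityMatrix:
    """Jaccard similarity of the rows' neighbor sets.

    For rows i and j with neighbor sets N_i, N_j:
    J = N11 / (N01 + N10 + N11) with N11 = |N_i & N_j|; pairs where both
    sets are empty score 0 (no evidence of similarity).
    """
    M = A.values.astype(np.int64)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    vals = np.divide(inter, union, out=np.zeros_like(inter, dtype=float), where=union > 0)
    return SimilarityMatrix(
        A.row_kind, A.row_ids, vals, source or f"network-{A.col_kind}"
    )


def maccs_fingerprint(drug: DrugSmiles) -> Fingerprint:
    """MACCS structural-key fingerprint (167 bits) of a drug.

    Raises ValueError on unparseable SMILES; callers computing a
    similarity matrix exclude such drugs and log them.
    """
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise ValueError(f"drug {drug.id!r}: unparseable SMILES {drug.smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    return Fingerprint(drug.id, np.array(fp, dtype=bool))


def tanimoto(f1: Fingerprint, f2: Fingerprint) -> float:
    """Tanimoto coefficient T = N11 / (N01 + N10 - N11), where N11 counts
    shared on-bits and N01/N10 the total on-bits of each fingerprint.
    Two all-zero fingerprints score 0."""
    if f1.bits.shape != f2.bits.shape:
        raise ValueError("fingerprint length mismatch")
    n11 = int(np.sum(f1.bits & f2.bits))
    denom = int(f1.bits.sum()) + int(f2.bits.sum()) - n11
    return n11 / denom if denom else 0.0


def fingerprint_similarity(drugs: Sequence[DrugSmiles]) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity over MACCS fingerprints.

    Drugs whose SMILES cannot be parsed are logged and score 0 against
    everything (diagonal included).
    """
    n = len(drugs)
    fps: list[Fingerprint | None] = []
    for d in drugs:
        try:
            fps.append(maccs_fingerprint(d))
        except ValueError as exc:
            logger.warning("excluding drug from fingerprint similarity: %s", exc)
            fps.append(None)
    ok = [i for i, f in enumerate(fps) if f is not None]
    vals = np.zeros((n, n))
    if ok:
        B = np.stack([fps[i].bits for i in ok]).astype(np.int64)
        inter = B @ B.T
        sizes = B.sum(axis=1)
        denom = sizes[:, None] + sizes[None, :] - inter
        sub = np.divide(inter, denom, out=np.zeros_like(inter, dtype=float), where=denom > 0)
        vals[np.ix_(ok, ok)] = sub
    return SimilarityMatrix(
        "drug", tuple(d.id for d in drugs), vals, "fingerprint"
    )


def _residue_counts(seq: str) -> Counter:
    return Counter(seq)


def protein_sequence_similarity(p1: ProteinSequence, p2: ProteinSequence) -> float:
    """Composition-based protein sequence similarity in [0, 1].

    With sequence lengths S1, S2 and E the total absolute difference of
    per-residue-type counts, the dissimilarity index is
    I = |S1 - S2| + 2E and the similarity L = (S1 + S2 - I) / (S1 + S2),
    clamped below at 0.  Identical sequences score 1.
    """
    c1, c2 = _residue_counts(p1.residues), _residue_counts(p2.residues)
    E = sum(abs(c1[a] - c2[a]) for a in set(c1) | set(c2))
    s1, s2 = len(p1), len(p2)
    I = abs(s1 - s2) + 2 * E
    return max(0.0, (s1 + s2 - I) / (s1 + s2))


def sequence_similarity_matrix(proteins: Sequence[ProteinSequence]) -> SimilarityMatrix:
    """Pairwise composition similarity over a protein collection."""
    n = len(proteins)
    counts = np.zeros((n, len(AMINO_ACIDS) + 1), dtype=np.int64)
    alpha = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for i, p in enumerate(proteins):
        for ch, c in _residue_counts(p.residues).items():
            counts[i, alpha.get(ch, len(AMINO_ACIDS))] = c
    sizes = counts.sum(axis=1)
    E = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
    I = np.abs(sizes[:, None] - sizes[None, :]) + 2 * E
    tot = sizes[:, None] + sizes[None, :]
    vals = np.clip((tot - I) / tot, 0.0, 1.0)
    return SimilarityMatrix(
        "target", tuple(p.id for p in proteins), vals, "sequence"
    )


def add_similarity_edges(
    scores: Iterable[SimilarityMatrix],
    threshold: float,
    existing: AssociationMatrix,
) -> list[tuple[str, str, float, str]]:
    """Similarity edges (i, j, best score, source) with i < j.

    A pair gets an edge iff the maximum score across sources strictly
    exceeds ``threshold`` AND the pair has no existing interaction.
    """
    scores = list(scores)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    ids = scores[0].ids
    for s in scores:
        if s.ids != ids:
            raise ValueError("similarity matrices disagree on entity ids")
    if existing.row_ids != ids or existing.col_ids != ids:
        raise ValueError("interaction matrix ids do not match similarity ids")
    stack = np.stack([s.values for s in scores])
    best = stack.max(axis=0)
    which = stack.argmax(axis=0)
    edges = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if best[i, j] > threshold and not existing.values[i, j]:
                edges.append(
                    (ids[i], ids[j], float(best[i, j]), scores[which[i, j]].source)
                )
    return edges
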