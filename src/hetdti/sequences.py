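"""Sequence tokenization and one-hot embedding for proteins and drugs.

Proteins are tokenized into overlapping k-mers over the canonical 20-letter
amino-acid alphabet; drug SMILES strings are tokenized losslessly into atom,
bond, branch, ring-closure and bracket-atom symbols.  Both are one-hot
encoded column-wise into a fixed-length channel x length matrix with an
explicit padding mask, the raw input of the convolutional feature extractor.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue codes outside the canonical alphabet (ambiguity / rare residues).
NONCANONICAL_RESIDUES = set("BJOUXZ")
UNK = "<unk>"

# Fixed 61-symbol SMILES vocabulary: organic-subset atoms (upper and
# aromatic lower case), halogens, common charged/bracket atoms, bonds,
# branches, ring-closure digits, stereo marks and an unknown bucket.
DEFAULT_SMILES_VOCAB: tuple[str, ...] = (
    "C", "N", "O", "S", "P", "F", "I", "B",
    "Cl", "Br",
    "c", "n", "o", "s", "p", "b",
    "[nH]", "[NH]", "[N+]", "[NH2+]", "[NH3+]", "[N-]", "[n+]",
    "[O-]", "[OH]", "[S-]", "[S+]", "[s+]", "[C@H]", "[C@@H]", "[C@]",
    "[C@@]", "[CH]", "[CH2]", "[Se]", "[Na+]", "[Cl-]", "[K+]", "[H]",
    "[Si]", "[P+]", "[B-]",
    "=", "#", "-", "+", "/", "\\", ":", ".", "%",
    "(", ")",
    "1", "2", "3", "4", "5", "6", "7",
    UNK,
)

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[A-Za-z]|\d|=|#|-|\+|/|\\|:|\.|\(|\)|@|\*|~|\$)"
)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a stable identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DrugSmiles:
    """A drug identified by a SMILES string, tokenized on construction."""

    id: str
    smiles: str
    tokens: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"drug {self.id!r}: empty SMILES")
        if not self.tokens:
            object.__setattr__(self, "tokens", tuple(tokenize_smiles(self.smiles)))

    def __len__(self) -> int:
        return len(self.tokens)


class Vocabulary:
    """Bijective token -> index map with JSON round-trip."""

    def __init__(self, tokens: Sequence[str]):
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.index = {t: i for i, t in enumerate(tokens)}
        self.tokens = tuple(tokens)

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        return self.index[token]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.index, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        index = json.loads(Path(path).read_text())
        tokens = sorted(index, key=index.__getitem__)
        if [index[t] for t in tokens] != list(range(len(tokens))):
            raise ValueError("vocabulary indices are not a bijection onto 0..size-1")
        return cls(tokens)


class KmerVocabulary(Vocabulary):
    """k-mer vocabulary over the amino-acid alphabet (optionally + UNK)."""

    def __init__(self, tokens: Sequence[str], k: int):
        super().__init__(tokens)
        self.k = k


def tokenize_protein(seq: ProteinSequence, k: int = 3) -> list[str]:
    """Overlapping k-mer windows of ``seq``, in sequence order.

    A sequence of length n yields n - k + 1 windows; k = 1 is the identity
    tokenization.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(seq.residues)
    if n < k:
        raise ValueError(
            f"protein {seq.id!r}: length {n} shorter than k-mer size {k}"
        )
    return [seq.residues[i : i + k] for i in range(n - k + 1)]


def build_kmer_vocabulary(
    sequences: Iterable[ProteinSequence],
    k: int = 3,
    mode: Literal["full", "corpus"] = "full",
    residue_policy: Literal["unk", "error", "drop"] = "unk",
) -> KmerVocabulary:
    """k-mer token -> index map, lexicographically ordered.

    ``full`` mode enumerates all 20**k canonical k-mers (size exactly 20^k)
    so embeddings do not depend on the corpus; ``corpus`` mode restricts to
    k-mers observed in ``sequences``.  Non-canonical residues are handled
    per ``residue_policy``: a shared UNK channel (appended only when the
    corpus actually contains such residues), a hard error, or dropped
    k-mers.
    """
    sequences = list(sequences)
    needs_unk = False
    if mode == "full":
        tokens = ["".join(p) for p in product(AMINO_ACIDS, repeat=k)]
        if residue_policy == "unk":
            needs_unk = any(
                NONCANONICAL_RESIDUES & set(s.residues) for s in sequences
            )
    elif mode == "corpus":
        seen: set[str] = set()
        n_seqs = 0
        for seq in sequences:
            n_seqs += 1
            for tok in tokenize_protein(seq, k):
                if any(c not in AMINO_ACIDS for c in tok):
                    if residue_policy == "error":
                        raise ValueError(
                            f"protein {seq.id!r}: non-canonical k-mer {tok!r}"
                        )
                    needs_unk = residue_policy == "unk"
                    continue  # routed to UNK or dropped at encode time
                seen.add(tok)
        if n_seqs == 0:
            raise ValueError("corpus mode requires a non-empty sequence collection")
        tokens = sorted(seen)
    else:
        raise ValueError(f"unknown vocabulary mode {mode!r}")
    if needs_unk:
        tokens.append(UNK)
    return KmerVocabulary(tokens, k)


def tokenize_smiles(smiles: str) -> list[str]:
    """Lossless SMILES tokenization.

    Two-letter halogens (Cl, Br) and bracket atoms ``[...]`` are single
    tokens; everything else is one character.  Concatenating the tokens
    reproduces the input exactly.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    depth = 0
    for ch in smiles:
        if ch == "[":
            depth += 1
            if depth > 1:
                raise ValueError(f"nested '[' in SMILES {smiles!r}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ']' in SMILES {smiles!r}")
    if depth != 0:
        raise ValueError(f"unbalanced '[' in SMILES {smiles!r}")
    tokens = _SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r} losslessly")
    return tokens


def build_smiles_vocabulary(
    drugs: Iterable[DrugSmiles] | None = None,
) -> Vocabulary:
    """Default frozen 61-token vocabulary, or one built from a drug corpus.

    A corpus-built vocabulary is the sorted set of observed tokens plus UNK,
    matching how the default list was assembled.
    """
    if drugs is None:
        return Vocabulary(DEFAULT_SMILES_VOCAB)
    seen: set[str] = set()
    for d in drugs:
        seen.update(d.tokens)
    return Vocabulary(sorted(seen) + [UNK])


@dataclass
class SequenceEmbedding:
    """One-hot encoded sequence: token indices plus a padding mask.

    ``indices[p]`` is the vocabulary index of position p (valid where
    ``mask[p]``); the dense channel x length matrix is materialized on
    demand.  Unmasked columns are exactly one-hot; padded columns all-zero.
    """

    entity_id: str
    indices: np.ndarray  # (L,) int32; arbitrary where mask is False
    mask: np.ndarray  # (L,) bool
    channels: int

    @property
    def length(self) -> int:
        return self.indices.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def matrix(self) -> np.ndarray:
        """Dense C x L one-hot matrix (padded columns are all-zero)."""
        m = np.zeros((self.channels, self.length))
        cols = np.flatnonzero(self.mask)
        m[self.indices[cols], cols] = 1.0
        return m

    def decode(self, vocab: Vocabulary) -> list[str]:
        return [vocab.tokens[i] for i in self.indices[self.mask]]


def _encode_tokens(
    entity_id: str,
    tokens: Sequence[str],
    vocab: Vocabulary,
    max_len: int,
    unknown: Literal["unk", "error", "drop"],
) -> SequenceEmbedding:
    if max_len < 1:
        raise ValueError("maximum length must be >= 1")
    idx: list[int] = []
    for tok in tokens:
        if tok in vocab:
            idx.append(vocab[tok])
        elif unknown == "unk" and UNK in vocab:
            idx.append(vocab[UNK])
        elif unknown == "drop":
            continue
        else:
            raise KeyError(f"{entity_id!r}: token {tok!r} not in vocabulary")
    idx = idx[:max_len]  # truncate from the right
    if not idx:
        raise ValueError(f"{entity_id!r}: no encodable tokens")
    indices = np.zeros(max_len, dtype=np.int32)
    mask = np.zeros(max_len, dtype=bool)
    indices[: len(idx)] = idx
    mask[: len(idx)] = True
    return SequenceEmbedding(entity_id, indices, mask, vocab.size)


def encode_protein(
    seq: ProteinSequence,
    vocab: KmerVocabulary,
    max_len: int,
    unknown: Literal["unk", "error", "drop"] = "unk",
) -> SequenceEmbedding:
    """One-hot encode a protein's overlapping k-mers, padded/truncated to
    ``max_len`` columns.  min(n-k+1, max_len) columns are unmasked."""
    return _encode_tokens(
        seq.id, tokenize_protein(seq, vocab.k), vocab, max_len, unknown
    )


def encode_drug(
    drug: DrugSmiles,
    vocab: Vocabulary,
    max_len: int,
    unknown: Literal["unk", "error", "drop"] = "unk",
) -> SequenceEmbedding:
    """One-hot encode a drug's SMILES tokens, padded/truncated to ``max_len``."""
    return _encode_tokens(drug.id, drug.tokens, vocab, max_len, unknown)


def default_max_length(lengths: Sequence[int], multiple: int = 8) -> int:
    """95th-percentile length rounded up to a multiple of ``multiple``."""
    q = float(np.percentile(np.asarray(lengths, dtype=float), 95))
    return max(multiple, int(np.ceil(q / multiple) * multiple))


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Proteins from FASTA; the id is the first word of the header."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(r.id, str(r.seq).upper()) for r in records]


def read_smiles_tsv(path: str | Path) -> list[DrugSmiles]:
    """Drugs from a two-column TSV ``drug_id<TAB>smiles`` (no header)."""
    drugs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 'id<TAB>smiles', got {line!r}")
        drugs.append(DrugSmiles(parts[0], parts[1]))
    if not drugs:
        raise ValueError(f"no drugs in {path}")
    return drugs
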