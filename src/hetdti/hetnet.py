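"""The heterogeneous drug-target network G = (V, E, R).

Nodes are drugs and protein targets (diseases and side effects enter only
through the similarity computation, never as graph nodes).  R holds five
typed relations, each stored as a boolean adjacency over the full node
set, drugs first then targets, lexicographic within each kind:

* drug-drug interaction
* drug-drug similarity
* drug-target interaction
* target-target interaction
* target-target similarity

Self-loops are not stored; propagation works on S~_r = I + S_r with the
degree matrix taken from S~_r so normalization is always well defined.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import AssociationMatrix

logger = logging.getLogger(__name__)

RELATIONS = (
    "drug_drug_interaction",
    "drug_drug_similarity",
    "drug_target_interaction",
    "target_target_interaction",
    "target_target_similarity",
)


@dataclass
class HeterogeneousNetwork:
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    relations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.drug_ids) & set(self.target_ids):
            clash = sorted(set(self.drug_ids) & set(self.target_ids))[:5]
            raise ValueError(f"node ids shared between kinds: {clash}")
        n = self.n_nodes
        for name, S in self.relations.items():
            if name not in RELATIONS:
                raise ValueError(f"unknown relation {name!r}")
            S = np.asarray(S, dtype=bool)
            if S.shape != (n, n):
                raise ValueError(f"relation {name}: shape {S.shape} != ({n},{n})")
            if not np.array_equal(S, S.T):
                raise ValueError(f"relation {name} is not symmetric")
            if S.diagonal().any():
                raise ValueError(f"relation {name} stores self-loops")
            self.relations[name] = S
        for name in RELATIONS:
            self.relations.setdefault(name, np.zeros((n, n), dtype=bool))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_targets

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.drug_ids + self.target_ids

    def node_index(self, entity_id: str) -> int:
        return self.node_ids.index(entity_id)

    # -- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write one TSV edge list per relation plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = self.node_ids
        files = {}
        for name, S in self.relations.items():
            fname = f"{name}.tsv"
            rows, cols = np.nonzero(np.triu(S, k=1))
            with open(directory / fname, "w") as fh:
                for i, j in zip(rows, cols):
                    fh.write(f"{ids[i]}\t{ids[j]}\n")
            files[name] = fname
        manifest = {
            "drug_ids": list(self.drug_ids),
            "target_ids": list(self.target_ids),
            "relations": files,
        }
        (directory / "network.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "HeterogeneousNetwork":
        directory = Path(directory)
        manifest = json.loads((directory / "network.json").read_text())
        drug_ids = tuple(manifest["drug_ids"])
        target_ids = tuple(manifest["target_ids"])
        ids = drug_ids + target_ids
        pos = {x: i for i, x in enumerate(ids)}
        n = len(ids)
        relations = {}
        for name, fname in manifest["relations"].items():
            S = np.zeros((n, n), dtype=bool)
            text = (directory / fname).read_text()
            for line in text.splitlines():
                if not line.strip():
                    continue
                a, b = line.split("\t")
                S[pos[a], pos[b]] = S[pos[b], pos[a]] = True
            relations[name] = S
        return cls(drug_ids, target_ids, relations)


def to_networkx(network: HeterogeneousNetwork):
    """Export to a networkx multigraph (one keyed edge per relation) for
    visualization or interchange (e.g. ``nx.write_graphml``)."""
    import networkx as nx

    G = nx.MultiGraph()
    for i, node in enumerate(network.node_ids):
        G.add_node(node, kind="drug" if i < network.n_drugs else "target")
    ids = network.node_ids
    for name, S in network.relations.items():
        rows, cols = np.nonzero(np.triu(S, k=1))
        for i, j in zip(rows, cols):
            G.add_edge(ids[i], ids[j], key=name, relation=name)
    return G


def load_association(
    path: str | Path,
    row_kind: str,
    col_kind: str,
    row_ids: tuple[str, ...] | None = None,
    col_ids: tuple[str, ...] | None = None,
) -> AssociationMatrix:
    """Read a boolean association matrix from TSV.

    Accepts either a dense 0/1 matrix (header = column ids, first column =
    row ids) or a two-column edge list.  When reference id lists are
    supplied, unknown ids raise; otherwise ids are collected from the file
    and ordered lexicographically.  Duplicate edges collapse with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        if row_ids is None or col_ids is None:
            raise ValueError(f"{path}: empty file and no reference id lists")
        return AssociationMatrix(
            row_kind, col_kind, row_ids, col_ids,
            np.zeros((len(row_ids), len(col_ids)), dtype=bool),
        )
    first = lines[0].split("\t")
    if len(first) > 2 or (row_ids is not None and first[0] == ""):
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.all(np.isin(vals, [0, 1])):
            bad = np.unique(vals[~np.isin(vals, [0, 1])])
            raise ValueError(f"{path}: non-binary values {bad[:5]}")
        return AssociationMatrix(
            row_kind, col_kind, tuple(map(str, df.index)),
            tuple(map(str, df.columns)), vals.astype(bool),
        )
    pairs: list[tuple[str, str]] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 2 columns, got {line!r}")
        pairs.append((parts[0], parts[1]))
    if len(set(pairs)) != len(pairs):
        warnings.warn(f"{path}: duplicate edges collapsed")
        logger.warning("%s: duplicate edges collapsed", path)
    r_ids = row_ids or tuple(sorted({a for a, _ in pairs}))
    c_ids = col_ids or tuple(sorted({b for _, b in pairs}))
    rpos = {x: i for i, x in enumerate(r_ids)}
    cpos = {x: i for i, x in enumerate(c_ids)}
    M = np.zeros((len(r_ids), len(c_ids)), dtype=bool)
    for a, b in pairs:
        if a not in rpos:
            raise KeyError(f"{path}: unknown {row_kind} id {a!r}")
        if b not in cpos:
            raise KeyError(f"{path}: unknown {col_kind} id {b!r}")
        M[rpos[a], cpos[b]] = True
        if row_kind == col_kind:
            M[cpos[b], rpos[a]] = True
    return AssociationMatrix(row_kind, col_kind, r_ids, c_ids, M)


def assemble_network(
    drug_ids: tuple[str, ...],
    target_ids: tuple[str, ...],
    drug_drug: AssociationMatrix,
    drug_target: AssociationMatrix,
    target_target: AssociationMatrix,
    drug_sim_edges: list[tuple[str, str, float, str]] = (),
    target_sim_edges: list[tuple[str, str, float, str]] = (),
) -> HeterogeneousNetwork:
    """Build G from interaction matrices plus thresholded similarity edges.

    Similarity edges never coexist with an interaction edge for the same
    pair (the edge-insertion rule already excludes interacting pairs; this
    is revalidated here).
    """
    drug_ids = tuple(sorted(drug_ids))
    target_ids = tuple(sorted(target_ids))
    nd, nt = len(drug_ids), len(target_ids)
    n = nd + nt
    dpos = {x: i for i, x in enumerate(drug_ids)}
    tpos = {x: nd + i for i, x in enumerate(target_ids)}

    def block(A: AssociationMatrix, rpos, cpos) -> np.ndarray:
        S = np.zeros((n, n), dtype=bool)
        for a, i in zip(A.row_ids, range(len(A.row_ids))):
            for b, j in zip(A.col_ids, range(len(A.col_ids))):
                if A.values[i, j] and a != b:
                    S[rpos[a], cpos[b]] = S[cpos[b], rpos[a]] = True
        return S

    relations = {
        "drug_drug_interaction": block(drug_drug, dpos, dpos),
        "drug_target_interaction": block(drug_target, dpos, tpos),
        "target_target_interaction": block(target_target, tpos, tpos),
    }
    for name, edges, pos, inter in (
        ("drug_drug_similarity", drug_sim_edges, dpos, relations["drug_drug_interaction"]),
        ("target_target_similarity", target_sim_edges, tpos, relations["target_target_interaction"]),
    ):
        S = np.zeros((n, n), dtype=bool)
        for a, b, _score, _src in edges:
            i, j = pos[a], pos[b]
            if inter[i, j]:
                raise ValueError(
                    f"{name}: similarity edge ({a}, {b}) duplicates an interaction"
                )
            S[i, j] = S[j, i] = True
        relations[name] = S
    return HeterogeneousNetwork(drug_ids, target_ids, relations)


def degree_matrix(S: np.ndarray, with_self_loops: bool = True) -> np.ndarray:
    """Diagonal degree matrix of S~ = I + S (default) or of S itself."""
    S = np.asarray(S)
    deg = S.sum(axis=1).astype(float)
    if with_self_loops:
        deg = deg + 1.0
    return np.diag(deg)


def normalized_adjacency(S: np.ndarray) -> np.ndarray:
    """Symmetric normalization A^{-1/2} S~ A^{-1/2} with S~ = I + S."""
    S_tilde = np.asarray(S, dtype=float) + np.eye(S.shape[0])
    d = S_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return S_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
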