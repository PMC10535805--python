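"""Seeded generator of complete synthetic input bundles.

Emulates the input bundle the pipeline consumes — drug SMILES, protein
sequences, and six boolean association networks (drug-disease, drug-drug,
drug-target, drug-side-effect, target-disease, target-target) — with a
planted latent-community structure:

* drugs and targets are assigned to communities; pairwise edges are drawn
  Bernoulli(p_in) within a community and Bernoulli(p_out) across, so the
  drug-target matrix carries a recoverable signal;
* diseases and side effects also belong to communities and associate
  preferentially with same-community drugs/targets, making the
  network-Jaccard similarities community-informative;
* SMILES are drawn from a curated library of valid scaffold templates with
  random substituent swaps, scaffolds partitioned by community so MACCS /
  Tanimoto similarity is community-informative;
* protein sequences get community-biased residue composition so the
  length/composition sequence similarity is community-informative.

Everything derives from one seeded generator: the same seed reproduces
the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sequences import AMINO_ACIDS, DrugSmiles, ProteinSequence
from .similarity import AssociationMatrix

# Scaffold templates ({R} marks the substitution point) and substituents.
# Every combination is a valid, parseable SMILES of >= 12 tokens.
SCAFFOLDS: tuple[str, ...] = (
    "CC(=O)Nc1ccc({R})cc1",
    "O=C({R})Oc1ccccc1C(=O)O",
    "c1ccc2c(c1)[nH]c1ccc({R})cc12",
    "CN1CCN(c2ccc({R})cc2)CC1",
    "O=C(Nc1ccccc1{R})c1ccccc1",
    "CC(C)Cc1ccc(C(C)C(=O)O{R})cc1",
    "c1ccc(-c2ccc({R})cc2)cc1",
    "O=S(=O)(N{R})c1ccc(N)cc1",
    "CC1=CC(=O)C=C(C1=O)C({R})C",
    "c1cnc2[nH]cc(C{R})c2c1",
    "COc1cc2c(cc1OC)CC({R})N2",
    "O=C1NC(=O)C(c2ccccc2)({R})N1",
    "CC(=O)Oc1ccccc1C(=O)N{R}",
    "c1ccc(CN2CCC({R})CC2)cc1",
    "O=c1[nH]c(=O)n(C{R})c2ncn(C)c12",
    "CC(N)Cc1ccc({R})c(O)c1",
    "O=C(O)CCc1ccc({R})cc1O",
    "Clc1ccc(C(c2ccccc2)N2CCN({R})CC2)cc1",
    "CC1(C)SC2C(NC(=O)C{R})C(=O)N2C1C(=O)O",
    "c1ccc(-n2cnc3ccc({R})cc32)cc1",
    "COc1ccc2cc(C(C)C(=O)O{R})ccc2c1",
    "NC(=O)c1ccc({R})nc1",
    "CCN(CC)C(=O)c1cc({R})ccc1N",
    "Oc1ccc2c(c1)OC(c1ccccc1{R})C2",
)
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "F", "Br",
    "C(=O)O", "C(=O)N", "CO", "C(C)C", "CCO", "C#N",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark (desk scale)."""

    n_drugs: int = 60
    n_targets: int = 90
    n_diseases: int = 150
    n_side_effects: int = 120
    n_communities: int = 3
    p_in: float = 0.25
    p_out: float = 0.02
    protein_length_range: tuple[int, int] = (60, 140)
    composition_bias: float = 3.0  # enrichment of community residues
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        for name in ("n_drugs", "n_targets", "n_diseases", "n_side_effects",
                     "n_communities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.protein_length_range
        if not (10 <= lo <= hi):
            raise ValueError("protein lengths must satisfy 10 <= lo <= hi")


@dataclass
class Bundle:
    """One complete synthetic input set plus its hidden community labels."""

    config: SyntheticConfig
    drugs: list[DrugSmiles]
    proteins: list[ProteinSequence]
    drug_disease: AssociationMatrix
    drug_drug: AssociationMatrix
    drug_target: AssociationMatrix
    drug_side_effect: AssociationMatrix
    target_disease: AssociationMatrix
    target_target: AssociationMatrix
    drug_communities: np.ndarray = field(repr=False, default=None)
    target_communities: np.ndarray = field(repr=False, default=None)

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.drugs)

    @property
    def target_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.proteins)

    def labeled_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Every (drug_idx, target_idx) cell with its 0/1 label."""
        nd, nt = len(self.drugs), len(self.proteins)
        pairs = np.stack(np.meshgrid(np.arange(nd), np.arange(nt), indexing="ij"),
                         axis=-1).reshape(-1, 2)
        labels = self.drug_target.values.astype(int).reshape(-1)
        return pairs, labels

    def write(self, directory: str | Path) -> None:
        """File layout the CLI consumes: FASTA, SMILES TSV, six relation
        TSV edge lists, and a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "proteins.fasta", "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.id}\n{p.residues}\n")
        with open(directory / "drugs.tsv", "w") as fh:
            for d in self.drugs:
                fh.write(f"{d.id}\t{d.smiles}\n")
        mats = {
            "drug_disease": self.drug_disease,
            "drug_drug": self.drug_drug,
            "drug_target": self.drug_target,
            "drug_side_effect": self.drug_side_effect,
            "target_disease": self.target_disease,
            "target_target": self.target_target,
        }
        for name, A in mats.items():
            with open(directory / f"{name}.tsv", "w") as fh:
                rows, cols = np.nonzero(A.values)
                for i, j in zip(rows, cols):
                    if A.row_kind == A.col_kind and i >= j:
                        continue
                    fh.write(f"{A.row_ids[i]}\t{A.col_ids[j]}\n")
        manifest = {
            "proteins": "proteins.fasta",
            "drugs": "drugs.tsv",
            "relations": {k: f"{k}.tsv" for k in mats},
            "ids": {
                "drug": list(self.drug_ids),
                "target": list(self.target_ids),
                "disease": list(self.drug_disease.col_ids),
                "side_effect": list(self.drug_side_effect.col_ids),
            },
            "seed": self.config.seed,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _block_bernoulli(rng, comm_a, comm_b, p_in, p_out, symmetric=False):
    same = comm_a[:, None] == comm_b[None, :]
    p = np.where(same, p_in, p_out)
    M = rng.random(p.shape) < p
    if symmetric:
        M = np.triu(M, k=1)
        M = M | M.T
    return M


def generate_dataset(config: SyntheticConfig | None = None) -> Bundle:
    """Draw a full input bundle under the planted-community model."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    nc = config.n_communities
    d_comm = rng.integers(0, nc, config.n_drugs)
    t_comm = rng.integers(0, nc, config.n_targets)
    e_comm = rng.integers(0, nc, config.n_diseases)
    s_comm = rng.integers(0, nc, config.n_side_effects)

    drug_ids = tuple(f"D{i:03d}" for i in range(config.n_drugs))
    target_ids = tuple(f"T{i:03d}" for i in range(config.n_targets))
    disease_ids = tuple(f"E{i:03d}" for i in range(config.n_diseases))
    se_ids = tuple(f"S{i:03d}" for i in range(config.n_side_effects))

    # drugs: community-partitioned scaffolds + random substituents
    scaff_groups = [list(range(g, len(SCAFFOLDS), nc)) for g in range(nc)]
    drugs = []
    for i, c in enumerate(d_comm):
        group = scaff_groups[c % len(scaff_groups)] or list(range(len(SCAFFOLDS)))
        scaffold = SCAFFOLDS[group[rng.integers(len(group))]]
        sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        drugs.append(DrugSmiles(drug_ids[i], scaffold.replace("{R}", sub)))

    # proteins: residue composition enriched in a community-specific subset
    n_aa = len(AMINO_ACIDS)
    comm_weights = []
    for c in range(nc):
        w = np.ones(n_aa)
        favored = rng.choice(n_aa, size=6, replace=False)
        w[favored] *= config.composition_bias
        comm_weights.append(w / w.sum())
    lo, hi = config.protein_length_range
    proteins = []
    for i, c in enumerate(t_comm):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(
            np.array(list(AMINO_ACIDS))[rng.choice(n_aa, size=length, p=comm_weights[c])]
        )
        proteins.append(ProteinSequence(target_ids[i], seq))

    p_in, p_out = config.p_in, config.p_out
    mk = AssociationMatrix
    bundle = Bundle(
        config=config,
        drugs=drugs,
        proteins=proteins,
        drug_disease=mk("drug", "disease", drug_ids, disease_ids,
                        _block_bernoulli(rng, d_comm, e_comm, p_in, p_out)),
        drug_drug=mk("drug", "drug", drug_ids, drug_ids,
                     _block_bernoulli(rng, d_comm, d_comm, p_in, p_out, symmetric=True)),
        drug_target=mk("drug", "target", drug_ids, target_ids,
                       _block_bernoulli(rng, d_comm, t_comm, p_in, p_out)),
        drug_side_effect=mk("drug", "side_effect", drug_ids, se_ids,
                            _block_bernoulli(rng, d_comm, s_comm, p_in, p_out)),
        target_disease=mk("target", "disease", target_ids, disease_ids,
                          _block_bernoulli(rng, t_comm, e_comm, p_in, p_out)),
        target_target=mk("target", "target", target_ids, target_ids,
                         _block_bernoulli(rng, t_comm, t_comm, p_in, p_out, symmetric=True)),
        drug_communities=d_comm,
        target_communities=t_comm,
    )
    return bundle


def null_config(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """The matched no-signal condition: p_in lowered to p_out so no
    community structure is planted (downstream AUC should hover at 0.5)."""
    config = config or SyntheticConfig()
    p = 0.5 * (config.p_in + config.p_out)
    return replace(config, p_in=p, p_out=p)


def generate_worked_toys() -> dict:
    """Fixed micro-fixtures used across the unit tests (stable contents)."""
    fp_a = np.zeros(167, dtype=bool)
    fp_a[[1, 3]] = True
    fp_b = np.zeros(167, dtype=bool)
    fp_b[[2, 3]] = True
    return {
        "kmer5": ProteinSequence("toy_kmer5", "MKVLG"),
        "jac": ({"a", "b", "c"}, {"b", "c", "d"}),
        "fp_pair": (fp_a, fp_b),
        "protein_pair": (
            ProteinSequence("toy_p1", "AAAA"),
            ProteinSequence("toy_p2", "AAAC"),
        ),
        "graph2": np.array([[0, 1], [1, 0]], dtype=bool),
    }


def load_bundle(directory: str | Path) -> Bundle:
    """Re-read a bundle previously written with :meth:`Bundle.write`."""
    from .hetnet import load_association
    from .sequences import read_fasta, read_smiles_tsv

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    drugs = read_smiles_tsv(directory / manifest["drugs"])
    proteins = read_fasta(directory / manifest["proteins"])
    ids = manifest["ids"]
    kinds = {
        "drug_disease": ("drug", "disease"),
        "drug_drug": ("drug", "drug"),
        "drug_target": ("drug", "target"),
        "drug_side_effect": ("drug", "side_effect"),
        "target_disease": ("target", "disease"),
        "target_target": ("target", "target"),
    }
    mats = {}
    for name, (rk, ck) in kinds.items():
        mats[name] = load_association(
            directory / manifest["relations"][name], rk, ck,
            row_ids=tuple(ids[rk]), col_ids=tuple(ids[ck]),
        )
    return Bundle(
        config=SyntheticConfig(seed=manifest.get("seed", 0)),
        drugs=drugs, proteins=proteins,
        **mats,
    )
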