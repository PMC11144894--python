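"""Molecular graph input and DDI table I/O.

Drugs arrive as SMILES strings.  :func:`parse_smiles` turns one into a
:class:`MolecularGraph` over heavy atoms (hydrogens stay implicit):
nodes carry a fixed-width chemical descriptor vector, bonds of any order
become single undirected edges, because the encoder's message passing
uses no edge features.

The default :class:`AtomFeatureSchema` is a conventional descriptor set
(element, degree, implicit hydrogens, formal charge, hybridization,
valence, ring membership and a few boolean flags) sized to a total width
of 55.  The exact composition is this package's reconstruction of a
standard substructure-GNN input; it is configurable, and alternative
schemas are drop-in as long as their blocks sum to the declared width.

DDI datasets are plain delimited tables: a triple table with header
``drug_x  drug_y  relation`` and a companion drug map ``drug_id  smiles``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit's stderr chatter on bad SMILES

__all__ = [
    "MolecularGraph",
    "AtomFeatureSchema",
    "FeatureBlock",
    "DDITriple",
    "Polarity",
    "SmilesParseError",
    "TableFormatError",
    "default_schema",
    "parse_smiles",
    "featurize_atom",
    "normalize_features",
    "read_ddi_table",
    "write_ddi_table",
    "read_drug_map",
    "write_drug_map",
]


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


class TableFormatError(ValueError):
    pass


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class DDITriple:
    """One (drug_x, drug_y, relation) record; negatives are corrupted copies."""

    drug_x: str
    drug_y: str
    relation: int
    polarity: Polarity = Polarity.POSITIVE


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one molecule.

    ``edges`` holds each bond once as an unordered index pair; the dense
    symmetric adjacency used by the encoder is built on demand.
    """

    node_features: np.ndarray  # (n, d_in)
    edges: list[tuple[int, int]]
    smiles: str

    @property
    def n(self) -> int:
        return self.node_features.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for u, v in self.edges:
            a[u, v] = 1.0
            a[v, u] = 1.0
        return a

    def validate(self) -> None:
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on atom {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) out of range for n={self.n}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)


@dataclass(frozen=True)
class FeatureBlock:
    """One block of the atom descriptor: a one-hot vocabulary (with an
    implicit trailing catch-all slot) or a list of boolean flags."""

    name: str
    kind: str  # "onehot" | "flags"
    vocabulary: tuple = ()
    flags: tuple = ()

    @property
    def width(self) -> int:
        if self.kind == "onehot":
            return len(self.vocabulary) + 1  # + catch-all
        return len(self.flags)


@dataclass(frozen=True)
class AtomFeatureSchema:
    blocks: tuple[FeatureBlock, ...]

    @property
    def total_width(self) -> int:
        return sum(b.width for b in self.blocks)


_HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2", "UNSPECIFIED")


def default_schema() -> AtomFeatureSchema:
    """The 55-wide default atom descriptor."""
    return AtomFeatureSchema(blocks=(
        FeatureBlock("element", "onehot",
                     vocabulary=("C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "B")),
        FeatureBlock("degree", "onehot", vocabulary=(0, 1, 2, 3, 4, 5)),
        FeatureBlock("implicit_h", "onehot", vocabulary=(0, 1, 2, 3, 4)),
        FeatureBlock("formal_charge", "onehot", vocabulary=(-2, -1, 0, 1, 2)),
        FeatureBlock("hybridization", "onehot", vocabulary=_HYBRIDIZATIONS),
        FeatureBlock("valence", "onehot", vocabulary=(0, 1, 2, 3, 4, 5, 6)),
        FeatureBlock("ring_size", "flags",
                     flags=("ring3", "ring4", "ring5", "ring6", "ring7", "ring8")),
        FeatureBlock("misc", "flags",
                     flags=("is_aromatic", "is_in_ring", "is_chiral", "has_radical")),
    ))


def _atom_descriptor(atom: Chem.Atom) -> dict:
    hyb = str(atom.GetHybridization())
    if hyb == "S":  # rdkit reports bare 's' orbitals for some ions
        hyb = "UNSPECIFIED"
    return {
        "element": atom.GetSymbol(),
        "degree": atom.GetDegree(),
        "implicit_h": atom.GetTotalNumHs(),
        "formal_charge": atom.GetFormalCharge(),
        "hybridization": hyb,
        "valence": atom.GetTotalValence(),
        "ring3": atom.IsInRingSize(3),
        "ring4": atom.IsInRingSize(4),
        "ring5": atom.IsInRingSize(5),
        "ring6": atom.IsInRingSize(6),
        "ring7": atom.IsInRingSize(7),
        "ring8": atom.IsInRingSize(8),
        "is_aromatic": atom.GetIsAromatic(),
        "is_in_ring": atom.IsInRing(),
        "is_chiral": atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED,
        "has_radical": atom.GetNumRadicalElectrons() > 0,
    }


def featurize_atom(descriptor: dict, schema: AtomFeatureSchema | None = None) -> np.ndarray:
    """Encode one atom descriptor to a vector of length ``schema.total_width``.

    Unknown one-hot categories fold into each block's catch-all slot, so
    every one-hot block sums to exactly 1.
    """
    schema = schema or default_schema()
    parts = []
    for block in schema.blocks:
        vec = np.zeros(block.width)
        if block.kind == "onehot":
            value = descriptor[block.name]
            try:
                vec[block.vocabulary.index(value)] = 1.0
            except ValueError:
                vec[-1] = 1.0  # catch-all
        else:
            for i, flag in enumerate(block.flags):
                vec[i] = 1.0 if descriptor[flag] else 0.0
        parts.append(vec)
    return np.concatenate(parts)


def parse_smiles(smiles: str, schema: AtomFeatureSchema | None = None) -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom graph."""
    if not smiles:
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    schema = schema or default_schema()
    feats = np.array([featurize_atom(_atom_descriptor(a), schema)
                      for a in mol.GetAtoms()])
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    graph = MolecularGraph(node_features=feats, edges=edges, smiles=smiles)
    graph.validate()
    return graph


def normalize_features(graph: MolecularGraph, eps: float = 1e-5) -> MolecularGraph:
    """Per-node layer normalization of the descriptor vectors.

    Each row is centred and scaled to unit variance across the feature
    dimension (the learnable affine of a LayerNorm is the identity at
    initialization and this package keeps it fixed there; the trainable
    input projection that follows absorbs any affine rescaling).
    """
    x = graph.node_features
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    normed = (x - mu) / np.sqrt(var + eps)
    return MolecularGraph(node_features=normed, edges=list(graph.edges),
                          smiles=graph.smiles)


# ---------------------------------------------------------------------------
# delimited tables


@dataclass
class RowError:
    line_number: int
    message: str


def read_drug_map(path, delimiter: str = "\t") -> dict[str, str]:
    """Read a ``drug_id  smiles`` table into a dict (file order preserved)."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return out
        required = {"drug_id", "smiles"}
        if not required.issubset(reader.fieldnames):
            raise TableFormatError(
                f"drug map must have columns {sorted(required)}, got {reader.fieldnames}")
        for row in reader:
            out[row["drug_id"]] = row["smiles"]
    return out


def write_drug_map(path, drug_map: dict[str, str], delimiter: str = "\t") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["drug_id", "smiles"])
        for drug_id, smiles in drug_map.items():
            writer.writerow([drug_id, smiles])


def read_ddi_table(
    path,
    drug_map: dict[str, str],
    delimiter: str = "\t",
    skip_missing: bool = False,
) -> tuple[list[DDITriple], list[RowError]]:
    """Read a positive-triple table; rows citing unmapped drugs become errors.

    With ``skip_missing`` the offending rows are still reported in the
    error list but do not abort anything; without it the caller decides —
    nothing is silently dropped either way.
    """
    triples: list[DDITriple] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return triples, errors
        required = {"drug_x", "drug_y", "relation"}
        if not required.issubset(reader.fieldnames):
            raise TableFormatError(
                f"triple table must have columns {sorted(required)}, got {reader.fieldnames}")
        for i, row in enumerate(reader, start=2):
            missing = [d for d in (row["drug_x"], row["drug_y"]) if d not in drug_map]
            if missing:
                errors.append(RowError(i, f"no SMILES for drug(s) {missing}"))
                continue
            triples.append(DDITriple(row["drug_x"], row["drug_y"], int(row["relation"])))
    return triples, errors


def write_ddi_table(path, triples: Iterable[DDITriple], delimiter: str = "\t") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["drug_x", "drug_y", "relation"])
        for t in triples:
            writer.writerow([t.drug_x, t.drug_y, t.relation])
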