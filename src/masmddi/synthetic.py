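"""Self-contained synthetic DDI corpora with planted chemical motifs.

Real DDI corpora are large and externally licensed, so end-to-end
behaviour is exercised on generated ones.  Each synthetic drug is a
small branched alkane scaffold (4–12 carbons) onto which one or two
functional-group motifs from a fixed library — carboxylic acid, primary
amine, phenol, nitrile, aliphatic alcohol, chloro — are grafted.  An
ordered rulebook maps motif pairs to interaction types: the pair
(x, y) interacts with relation r exactly when x carries the rule's
first motif and y its second (directional, matching the order-sensitive
scorer).  Labels therefore depend only on the presence of specific
substructures, which is precisely the structural signal the soft-mask
encoder is built to find, and motif presence is recoverable by SMARTS
matching for verification.

``SyntheticCorpus.rule_closure()`` enumerates *every* pair the rulebook
labels, not only the sampled triples; using it as the known-positive
filter during negative sampling keeps sampled negatives truly
rule-violating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

from .chem_io import DDITriple, write_ddi_table, write_drug_map

__all__ = [
    "Motif",
    "MotifRulebook",
    "SyntheticCorpus",
    "GenerationError",
    "default_rulebook",
    "generate_drug",
    "generate_corpus",
    "label_by_rule",
    "has_motif",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Motif:
    """A graftable functional group: fragment SMILES (attachment atom is
    index 0) and the SMARTS pattern that detects it in a product."""

    name: str
    fragment: str
    smarts: str


_MOTIFS = (
    Motif("carboxylic_acid", "C(=O)O", "[CX3](=O)[OX2H1]"),
    Motif("primary_amine", "N", "[NX3;H2]"),
    Motif("phenol", "c1ccc(O)cc1", "[OX2H1]c1ccccc1"),
    Motif("nitrile", "C#N", "[CX2]#[NX1]"),
    Motif("alcohol", "O", "[CX4][OX2H1]"),
    Motif("chloro", "Cl", "[Cl]"),
)


@dataclass(frozen=True)
class MotifRulebook:
    """Ordered, directional labelling rules over a motif library.

    ``rules[k] = (motif_a, motif_b, relation)``: a pair (x, y) receives
    the relation of the *first* rule whose motif_a occurs in x and
    motif_b in y.  ``noise_rate`` is the fraction of generated triples
    whose relation is deliberately re-rolled.
    """

    motifs: tuple[Motif, ...]
    rules: tuple[tuple[str, str, int], ...]
    noise_rate: float = 0.0

    def __post_init__(self):
        names = {m.name for m in self.motifs}
        for a, b, rel in self.rules:
            if a not in names or b not in names:
                raise ValueError(f"rule ({a},{b}) references unknown motif")
        rels = sorted({r for _, _, r in self.rules})
        if rels != list(range(len(rels))):
            raise ValueError("relation ids must be dense 0..n_rel-1")

    @property
    def n_relations(self) -> int:
        return 1 + max(r for _, _, r in self.rules)

    def motif(self, name: str) -> Motif:
        return next(m for m in self.motifs if m.name == name)


def default_rulebook(n_relations: int = 3, noise_rate: float = 0.0) -> MotifRulebook:
    """Directional rules pairing the six library motifs, first
    ``n_relations`` of: (acid→amine), (phenol→nitrile), (alcohol→chloro),
    (amine→phenol), (nitrile→acid), (chloro→alcohol)."""
    pairs = [
        ("carboxylic_acid", "primary_amine"),
        ("phenol", "nitrile"),
        ("alcohol", "chloro"),
        ("primary_amine", "phenol"),
        ("nitrile", "carboxylic_acid"),
        ("chloro", "alcohol"),
    ]
    if not 1 <= n_relations <= len(pairs):
        raise ValueError(f"n_relations must be in 1..{len(pairs)}")
    rules = tuple((a, b, r) for r, (a, b) in enumerate(pairs[:n_relations]))
    return MotifRulebook(motifs=_MOTIFS, rules=rules, noise_rate=noise_rate)


def has_motif(smiles: str, motif: Motif) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return mol.HasSubstructMatch(Chem.MolFromSmarts(motif.smarts))


def label_by_rule(smiles_x: str, smiles_y: str,
                  rulebook: MotifRulebook) -> int | None:
    """Relation of the first firing rule, or None (rule order ties break)."""
    for a, b, rel in rulebook.rules:
        if has_motif(smiles_x, rulebook.motif(a)) and \
           has_motif(smiles_y, rulebook.motif(b)):
            return rel
    return None


def _build_scaffold(rng: np.random.Generator, size_range: tuple[int, int]) -> Chem.RWMol:
    """Linear alkane of random length with an optional methyl/ethyl branch."""
    length = int(rng.integers(size_range[0], size_range[1] + 1))
    mol = Chem.RWMol()
    idx = [mol.AddAtom(Chem.Atom(6)) for _ in range(length)]
    for i in range(length - 1):
        mol.AddBond(idx[i], idx[i + 1], Chem.BondType.SINGLE)
    if length >= 5 and rng.random() < 0.5:
        branch_len = int(rng.integers(1, 3))
        anchor = int(rng.integers(1, length - 1))
        prev = anchor
        for _ in range(branch_len):
            a = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(prev, a, Chem.BondType.SINGLE)
            prev = a
    return mol


def generate_drug(
    rng: np.random.Generator,
    rulebook: MotifRulebook,
    size_range: tuple[int, int] = (4, 12),
    motif_names: list[str] | None = None,
    max_retries: int = 20,
) -> str:
    """One synthetic drug: scaffold plus grafted motifs, as canonical SMILES.

    ``motif_names`` fixes which motifs to graft; by default one or two
    are drawn from the rulebook's library (two with probability 0.7 —
    dense enough that rule-consistent pairs are plentiful).
    """
    if motif_names is None:
        k = 2 if rng.random() < 0.7 else 1
        picks = rng.choice(len(rulebook.motifs), size=k, replace=False)
        motif_names = [rulebook.motifs[int(i)].name for i in picks]
    for _ in range(max_retries):
        mol = _build_scaffold(rng, size_range)
        scaffold_atoms = mol.GetNumAtoms()
        sites = rng.choice(scaffold_atoms, size=len(motif_names), replace=False)
        ok = True
        for name, site in zip(motif_names, sites):
            frag = Chem.MolFromSmiles(rulebook.motif(name).fragment)
            offset = mol.GetNumAtoms()
            mol = Chem.RWMol(Chem.CombineMols(mol, frag))
            mol.AddBond(int(site), offset, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - retry on rare valence clash
            ok = False
        if not ok:
            continue
        smiles = Chem.MolToSmiles(mol)
        if all(has_motif(smiles, rulebook.motif(n)) for n in motif_names):
            return smiles
    raise GenerationError(f"could not assemble a drug with motifs {motif_names}")


@dataclass
class SyntheticCorpus:
    """A generated DDI corpus: drugs, sampled positive triples, and the
    rulebook that defines ground truth."""

    drug_map: dict[str, str]
    triples: list[DDITriple]
    rulebook: MotifRulebook
    seed: int
    noisy_indices: list[int] = field(default_factory=list)

    @property
    def drugs(self) -> list[str]:
        return list(self.drug_map)

    def rule_closure(self) -> set[tuple[str, str, int]]:
        """Every ordered pair the rulebook labels (the full positive set,
        a superset of the sampled triples); the negative-sampling filter."""
        closure = set()
        ids = list(self.drug_map)
        motif_cache = {
            d: {m.name for m in self.rulebook.motifs
                if has_motif(s, m)}
            for d, s in self.drug_map.items()
        }
        for x in ids:
            for y in ids:
                if x == y:
                    continue
                for a, b, rel in self.rulebook.rules:
                    if a in motif_cache[x] and b in motif_cache[y]:
                        closure.add((x, y, rel))
                        break
        return closure

    def write(self, directory) -> None:
        """Serialize to the package's table formats plus a rulebook YAML."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_drug_map(directory / "drugs.tsv", self.drug_map)
        write_ddi_table(directory / "triples.tsv", self.triples)
        doc = {
            "seed": self.seed,
            "noise_rate": self.rulebook.noise_rate,
            "motifs": [{"name": m.name, "fragment": m.fragment,
                        "smarts": m.smarts} for m in self.rulebook.motifs],
            "rules": [{"motif_a": a, "motif_b": b, "relation": r}
                      for a, b, r in self.rulebook.rules],
        }
        (directory / "rulebook.yaml").write_text(yaml.safe_dump(doc))


def generate_corpus(
    n_drugs: int = 60,
    n_relations: int = 3,
    n_triples: int = 600,
    noise_rate: float = 0.0,
    seed: int = 0,
    size_range: tuple[int, int] = (4, 12),
) -> SyntheticCorpus:
    """Generate a labelled corpus of ``n_drugs`` drugs and ``n_triples``
    positive triples sampled from the rulebook's consistent pairs.

    Exactly ``floor(noise_rate * n_triples)`` triples then have their
    relation re-rolled uniformly over the vocabulary.
    """
    if n_drugs < 4:
        raise ValueError("need at least 4 drugs")
    rng = np.random.default_rng(seed)
    rulebook = default_rulebook(n_relations, noise_rate)
    drug_map = {f"D{i:03d}": generate_drug(rng, rulebook, size_range)
                for i in range(n_drugs)}

    corpus = SyntheticCorpus(drug_map=drug_map, triples=[], rulebook=rulebook,
                             seed=seed)
    consistent = sorted(corpus.rule_closure())
    if len(consistent) < n_triples:
        raise GenerationError(
            f"only {len(consistent)} rule-consistent pairs for {n_triples} "
            "requested triples; increase n_drugs or lower n_triples")
    chosen = rng.choice(len(consistent), size=n_triples, replace=False)
    triples = [DDITriple(*consistent[int(i)]) for i in sorted(chosen)]

    n_noisy = int(noise_rate * n_triples)
    noisy_idx = sorted(rng.choice(n_triples, size=n_noisy, replace=False).tolist()) \
        if n_noisy else []
    for i in noisy_idx:
        t = triples[i]
        triples[i] = DDITriple(t.drug_x, t.drug_y,
                               int(rng.integers(rulebook.n_relations)))
    corpus.triples = triples
    corpus.noisy_indices = noisy_idx
    return corpus
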