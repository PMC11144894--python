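"""Training machinery: negative sampling, loss, schedule, splits, metrics.

A DDI corpus contains only observed (positive) interactions, so the
binary task is set up knowledge-graph style: each positive triple
(x, y, R) is paired with a corrupted copy in which exactly one of the
two drug slots is replaced by a different drug, the relation preserved,
at a 1:1 ratio.  Corruptions colliding with known positives are
resampled (bounded retries, then the other slot is tried) so that the
negatives are not accidentally true.

Two evaluation protocols are supported.  The *transductive* (warm-start)
split partitions triples 60/20/20, stratified by interaction type, with
every drug potentially seen in training.  The *inductive* (cold-start)
split instead removes 20% of the drugs from training entirely: triples
between two held-out drugs form the S1 test set, triples with exactly
one held-out drug form S2, and only triples between retained drugs are
used for training/validation.

Metrics (ACC, AUROC, AUPRC, F1) are computed via scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from .chem_io import DDITriple, Polarity

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "MetricReport",
    "NegativeSamplingError",
    "sample_negative",
    "sample_negatives",
    "bce_loss",
    "lr_at_epoch",
    "split_transductive",
    "split_inductive",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and architecture settings.

    Defaults follow the reference configuration: batches of 128 triples,
    Adam with lr = 5e-4 · 0.96^epoch and weight decay 5e-4, four encoder
    layers of width 128, a 0.5 decision threshold and 1:1 negative
    sampling.  ``dropout=None`` resolves to 0.2 for inductive (cold
    start) training and 0.0 otherwise; the rate applies to substructure
    embeddings just before the attention module.

    ``head_init_scale`` shrinks the initialization of the scoring head
    (the co-attention vector z and the relation matrices) so initial
    logits sit near zero.  With a full-scale head the untrained logits
    are large noise and the quickest loss reduction is to collapse the
    soft masks to zero — a saturated p≡0.5 fixed point the optimizer
    cannot leave; starting the head small removes that pressure while
    every gradient path stays live.

    The collapse is detectable (loss pinned at 2·ln 2, validation AUROC
    at chance), and for unlucky initializations it can still occur, so
    ``fit`` retrains from a deterministically re-derived initialization
    up to ``max_restarts`` times when it sees a collapsed run — the
    multi-start strategy standard for optimizers with known bad basins.
    """

    batch_size: int = 128
    base_lr: float = 5e-4
    lr_decay: float = 0.96
    weight_decay: float = 5e-4
    epochs: int = 100
    seed: int = 0
    neg_ratio: int = 1
    threshold: float = 0.5
    attention_module: bool = True
    channel_attention: bool = True
    dropout: float | None = None
    n_layers: int = 4
    hidden_dim: int = 128
    mask_dim: int | None = None
    coattn_dim: int | None = None
    head_init_scale: float = 0.01
    max_restarts: int = 3
    symmetrize: bool = False

    def __post_init__(self):
        if self.neg_ratio != 1:
            raise ValueError("neg_ratio is fixed at 1 (1:1 positive/negative balance)")
        for name in ("base_lr", "lr_decay", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "transductive"  # or "inductive"
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    unknown_drug_fraction: float = 0.2
    stratify_by_relation: bool = True

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 < self.unknown_drug_fraction < 1.0:
            raise ValueError("unknown_drug_fraction must be in (0,1)")
        if self.mode not in ("transductive", "inductive"):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class MetricReport:
    acc: float
    auroc: float
    auprc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "AUROC": self.auroc,
                "AUPRC": self.auprc, "F1": self.f1}


class NegativeSamplingError(RuntimeError):
    pass


def _corrupt(triple: DDITriple, side: str, replacement: str) -> DDITriple:
    if side == "x":
        return DDITriple(replacement, triple.drug_y, triple.relation, Polarity.NEGATIVE)
    return DDITriple(triple.drug_x, replacement, triple.relation, Polarity.NEGATIVE)


def sample_negative(
    triple: DDITriple,
    drug_pool: list[str],
    known_positives: set[tuple[str, str, int]],
    rng: np.random.Generator,
    max_retries: int = 50,
) -> DDITriple:
    """Corrupt one drug slot of a positive triple.

    The replacement keeps the relation, avoids self-pairs and avoids any
    triple present in ``known_positives``.  The side (x or y) is chosen
    uniformly; if one side cannot be corrupted within ``max_retries``
    draws the other side is tried before giving up.
    """
    if len(drug_pool) < 2:
        raise NegativeSamplingError("drug pool must contain at least 2 drugs")
    first = "x" if rng.random() < 0.5 else "y"
    for side in (first, "y" if first == "x" else "x"):
        kept = triple.drug_y if side == "x" else triple.drug_x
        for _ in range(max_retries):
            repl = drug_pool[int(rng.integers(len(drug_pool)))]
            if repl == kept or repl == (triple.drug_x if side == "x" else triple.drug_y):
                continue
            cand = _corrupt(triple, side, repl)
            if (cand.drug_x, cand.drug_y, cand.relation) not in known_positives:
                return cand
    raise NegativeSamplingError(
        f"could not corrupt ({triple.drug_x},{triple.drug_y},{triple.relation}): "
        "every candidate collides with a known positive")


def sample_negatives(
    triples: list[DDITriple],
    drug_pool: list[str],
    known_positives: set[tuple[str, str, int]],
    rng: np.random.Generator,
) -> list[DDITriple]:
    """One negative per positive, aligned by index (the 1:1 ratio)."""
    return [sample_negative(t, drug_pool, known_positives, rng) for t in triples]


def bce_loss(p_pos: np.ndarray, p_neg: np.ndarray, eps: float = 1e-7) -> float:
    """Paired binary cross-entropy: −mean(log p_pos + log(1−p_neg))."""
    p_pos = np.clip(np.asarray(p_pos, dtype=float), eps, 1.0 - eps)
    p_neg = np.clip(np.asarray(p_neg, dtype=float), eps, 1.0 - eps)
    if p_pos.shape != p_neg.shape:
        raise ValueError("positive and negative probability vectors must align")
    return float(-(np.log(p_pos) + np.log(1.0 - p_neg)).mean())


def lr_at_epoch(epoch: int, base_lr: float = 5e-4, decay: float = 0.96) -> float:
    """Exponentially decayed learning rate, lr = base · decay^epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return base_lr * decay**epoch


def _proportional_cut(n: int, spec: SplitSpec) -> tuple[int, int]:
    n_train = int(round(n * spec.train_fraction))
    n_val = int(round(n * spec.val_fraction))
    n_val = min(n_val, n - n_train)
    return n_train, n_val


def split_transductive(
    triples: list[DDITriple],
    spec: SplitSpec | None = None,
    seed: int = 0,
) -> tuple[list[DDITriple], list[DDITriple], list[DDITriple]]:
    """60/20/20 triple split, stratified by interaction type.

    Stratification keeps each relation's proportions within one triple
    of the requested fractions; relations with fewer than 5 triples
    trigger a fallback to a single global split.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(seed)
    groups: dict[int, list[int]] = {}
    for i, t in enumerate(triples):
        groups.setdefault(t.relation, []).append(i)

    stratify = spec.stratify_by_relation
    if stratify and any(len(g) < 5 for g in groups.values()):
        warnings.warn("some relation has < 5 triples; falling back to a global split")
        stratify = False
    if not stratify:
        groups = {0: list(range(len(triples)))}

    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for rel in sorted(groups):
        idx = np.array(groups[rel])
        rng.shuffle(idx)
        n_train, n_val = _proportional_cut(len(idx), spec)
        train_idx += idx[:n_train].tolist()
        val_idx += idx[n_train:n_train + n_val].tolist()
        test_idx += idx[n_train + n_val:].tolist()
    return ([triples[i] for i in sorted(train_idx)],
            [triples[i] for i in sorted(val_idx)],
            [triples[i] for i in sorted(test_idx)])


def split_inductive(
    triples: list[DDITriple],
    drugs: list[str],
    spec: SplitSpec | None = None,
    seed: int = 0,
) -> tuple[list[DDITriple], list[DDITriple], list[DDITriple], list[DDITriple], set[str]]:
    """Cold-start split: hold out a fraction of the *drugs*.

    Returns (train, val, s1_test, s2_test, unknown_drugs).  Triples
    between two retained drugs are split train/val in the spec's
    train:val ratio (stratified by relation); triples with both drugs
    held out form S1 and with exactly one held out form S2.
    """
    spec = spec or SplitSpec(mode="inductive")
    rng = np.random.default_rng(seed)
    drug_arr = np.array(sorted(set(drugs)))
    rng.shuffle(drug_arr)
    n_unknown = int(round(len(drug_arr) * spec.unknown_drug_fraction))
    unknown = set(drug_arr[:n_unknown].tolist())

    known_known: list[DDITriple] = []
    s1: list[DDITriple] = []
    s2: list[DDITriple] = []
    for t in triples:
        hits = (t.drug_x in unknown) + (t.drug_y in unknown)
        if hits == 2:
            s1.append(t)
        elif hits == 1:
            s2.append(t)
        else:
            known_known.append(t)
    if not s1 or not s2:
        warnings.warn("inductive split produced an empty S1 or S2 test set")

    tv_total = spec.train_fraction + spec.val_fraction
    tv_spec = replace(spec,
                      train_fraction=spec.train_fraction / tv_total,
                      val_fraction=spec.val_fraction / tv_total,
                      test_fraction=0.0)
    train, val, leftover = split_transductive(known_known, tv_spec, seed)
    train = sorted(train + leftover, key=lambda t: (t.drug_x, t.drug_y, t.relation))
    return train, val, s1, s2, unknown


def evaluate(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> MetricReport:
    """ACC/AUROC/AUPRC/F1 of probabilistic predictions.

    ACC and F1 use the strict ``p > threshold`` rule; the ranking
    metrics are threshold-free.  With only one class present, AUROC and
    AUPRC are undefined and reported as NaN with a warning.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probabilities.shape != labels.shape:
        raise ValueError("probabilities and labels must have equal length")
    predicted = (probabilities > threshold).astype(int)
    acc = float(accuracy_score(labels, predicted))
    f1 = float(f1_score(labels, predicted, zero_division=0.0))
    if len(np.unique(labels)) < 2:
        warnings.warn("only one class present; AUROC/AUPRC undefined (NaN)")
        auroc = auprc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, probabilities))
        auprc = float(average_precision_score(labels, probabilities))
    return MetricReport(acc=acc, auroc=auroc, auprc=auprc, f1=f1)
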