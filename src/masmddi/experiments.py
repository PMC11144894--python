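"""Canned evaluation protocols on synthetic corpora.

These helpers wire together corpus generation, splitting, fixed
evaluation negatives, model fitting and metric computation, so that the
warm-start (transductive), cold-start (inductive S1/S2) and
attention-ablation experiments are each a single call.  The test suite
and the reproduction script both run through them.

Evaluation negatives are sampled once per (split, seed) against the
corpus's rule closure — the full set of pairs the planted rulebook
labels — so a corrupted triple is never an unlisted true positive.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import DDIModel, DDIResults
from .synthetic import SyntheticCorpus
from .trainer import MetricReport, SplitSpec, TrainConfig, sample_negatives, \
    split_inductive, split_transductive

__all__ = ["run_transductive", "run_inductive"]


def _eval_seed(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([seed, salt])


def run_transductive(
    corpus: SyntheticCorpus,
    config: TrainConfig,
    seed: int,
) -> tuple[DDIResults, MetricReport]:
    """60/20/20 warm-start protocol; returns fitted results + test metrics."""
    config = replace(config, seed=seed)
    train, val, test = split_transductive(corpus.triples, SplitSpec(), seed)
    closure = corpus.rule_closure()
    model = DDIModel(train, corpus.drug_map, config=config,
                     n_relations=corpus.rulebook.n_relations,
                     known_positives=closure)
    results = model.fit(train=train, val=val, mode="transductive")
    test_neg = sample_negatives(test, corpus.drugs, closure, _eval_seed(seed, 1))
    return results, results.evaluate(test, test_neg)


def run_inductive(
    corpus: SyntheticCorpus,
    config: TrainConfig,
    seed: int,
) -> tuple[DDIResults, MetricReport | None, MetricReport | None]:
    """Cold-start protocol; returns results + S1 and S2 test metrics.

    S1/S2 metrics are None when the drug holdout leaves that test set
    empty (small corpora).
    """
    config = replace(config, seed=seed)
    train, val, s1, s2, _ = split_inductive(
        corpus.triples, corpus.drugs, SplitSpec(mode="inductive"), seed)
    closure = corpus.rule_closure()
    model = DDIModel(train, corpus.drug_map, config=config,
                     n_relations=corpus.rulebook.n_relations,
                     known_positives=closure)
    results = model.fit(train=train, val=val, mode="inductive")

    def _report(positives):
        if not positives:
            return None
        neg = sample_negatives(positives, corpus.drugs, closure,
                               _eval_seed(seed, 2))
        return results.evaluate(positives, neg)

    return results, _report(s1), _report(s2)
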