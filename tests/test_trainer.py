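"""Negative sampling, loss, schedule, splits and metric computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masmddi.chem_io import DDITriple, Polarity
from masmddi.trainer import (
    NegativeSamplingError,
    SplitSpec,
    TrainConfig,
    bce_loss,
    evaluate,
    lr_at_epoch,
    sample_negative,
    split_inductive,
    split_transductive,
)


def _triples(pairs):
    return [DDITriple(x, y, r) for x, y, r in pairs]


class TestSampleNegative:
    def test_corruption_changes_exactly_one_slot_and_keeps_relation(self, rng):
        pool = [f"d{i}" for i in range(8)]
        t = DDITriple("d0", "d1", 3)
        for _ in range(50):
            neg = sample_negative(t, pool, set(), rng)
            changed = (neg.drug_x != t.drug_x) + (neg.drug_y != t.drug_y)
            assert changed == 1
            assert neg.relation == 3
            assert neg.polarity is Polarity.NEGATIVE
            assert neg.drug_x != neg.drug_y

    def test_two_drug_pool_has_no_legal_corruption(self, rng):
        """Either corruption of (a,b) over pool {a,b} is a self-pair."""
        with pytest.raises(NegativeSamplingError):
            sample_negative(DDITriple("a", "b", 0), ["a", "b"], set(), rng)

    def test_known_positive_collisions_force_the_other_side(self, rng):
        """When every y-corruption is a known positive, the x side is
        corrupted instead."""
        known = {("a", "c", 0)}  # blocks the only y corruption
        for _ in range(10):
            neg = sample_negative(DDITriple("a", "b", 0), ["a", "b", "c"],
                                  known, rng)
            assert (neg.drug_x, neg.drug_y) == ("c", "b")

    def test_exhausted_pool_raises(self, rng):
        pool = ["a", "b", "c"]
        known = {(x, y, 0) for x in pool for y in pool}
        with pytest.raises(NegativeSamplingError):
            sample_negative(DDITriple("a", "b", 0), pool, known, rng)

    def test_seeded_sequence_is_reproducible(self):
        pool = [f"d{i}" for i in range(10)]
        t = DDITriple("d0", "d1", 1)
        seq1 = [sample_negative(t, pool, set(), np.random.default_rng(4))
                for _ in range(1)]
        seq2 = [sample_negative(t, pool, set(), np.random.default_rng(4))
                for _ in range(1)]
        assert seq1 == seq2


class TestBceLoss:
    def test_perfect_separation_is_near_zero(self):
        assert bce_loss([1 - 1e-7], [1e-7]) == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_half_is_two_log_two(self):
        assert bce_loss([0.5], [0.5]) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_mean_invariant_to_duplication(self, rng):
        p, q = rng.random(5), rng.random(5)
        assert bce_loss(np.tile(p, 2), np.tile(q, 2)) == pytest.approx(
            bce_loss(p, q))

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([0.5, 0.5], [0.5])


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 5e-4), (1, 4.8e-4), (10, 5e-4 * 0.96**10)])
    def test_closed_form(self, epoch, expected):
        assert lr_at_epoch(epoch) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        rates = [lr_at_epoch(t) for t in range(100)]
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestTransductiveSplit:
    def test_single_relation_hits_60_20_20(self):
        triples = _triples([(f"a{i}", f"b{i}", 0) for i in range(100)])
        train, val, test = split_transductive(triples, seed=1)
        assert (len(train), len(val), len(test)) == (60, 20, 20)

    def test_stratification_preserves_relation_mix(self):
        triples = _triples([(f"a{i}", f"b{i}", i % 2) for i in range(100)])
        train, val, test = split_transductive(triples, seed=2)
        for part, frac in ((train, 0.6), (val, 0.2), (test, 0.2)):
            for rel in (0, 1):
                count = sum(t.relation == rel for t in part)
                assert abs(count - frac * 50) <= 1

    def test_disjoint_cover_and_determinism(self):
        triples = _triples([(f"a{i}", f"b{i}", i % 3) for i in range(60)])
        parts1 = split_transductive(triples, seed=7)
        parts2 = split_transductive(triples, seed=7)
        assert parts1 == parts2
        merged = [t for part in parts1 for t in part]
        assert sorted(merged, key=lambda t: t.drug_x) == \
            sorted(triples, key=lambda t: t.drug_x)
        ids = [id(t) for part in parts1 for t in part]
        assert len(set((t.drug_x, t.drug_y, t.relation) for t in merged)) == 60

    def test_small_relation_falls_back_to_global_split(self):
        triples = _triples([("a", "b", 0)] * 30 + [("c", "d", 1)] * 2)
        with pytest.warns(UserWarning, match="falling back"):
            train, val, test = split_transductive(triples, seed=0)
        assert len(train) + len(val) + len(test) == 32


class TestInductiveSplit:
    @pytest.fixture()
    def corpus(self):
        rng = np.random.default_rng(8)
        drugs = [f"d{i}" for i in range(30)]
        triples = _triples([
            (drugs[rng.integers(30)], drugs[rng.integers(30)], int(rng.integers(2)))
            for _ in range(300)])
        return [t for t in triples if t.drug_x != t.drug_y], drugs

    def test_membership_contracts(self, corpus):
        triples, drugs = corpus
        train, val, s1, s2, unknown = split_inductive(triples, drugs, seed=3)
        assert len(unknown) == 6  # 20% of 30
        for t in train + val:
            assert t.drug_x not in unknown and t.drug_y not in unknown
        for t in s1:
            assert t.drug_x in unknown and t.drug_y in unknown
        for t in s2:
            assert (t.drug_x in unknown) + (t.drug_y in unknown) == 1

    def test_partition_accounts_for_every_triple(self, corpus):
        triples, drugs = corpus
        train, val, s1, s2, _ = split_inductive(triples, drugs, seed=3)
        key = lambda t: (t.drug_x, t.drug_y, t.relation)
        assert sorted(map(key, train + val + s1 + s2)) == \
            sorted(map(key, triples))

    def test_deterministic_under_seed(self, corpus):
        triples, drugs = corpus
        assert split_inductive(triples, drugs, seed=5) == \
            split_inductive(triples, drugs, seed=5)


# ---------------------------------------------------------------------------
# metric oracles


def brute_force_metrics(probs, labels, threshold=0.5):
    """Exhaustive definitions: confusion counts, pairwise concordance
    (ties half), and stepwise precision-weighted recall increments."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pred = (probs > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0

    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auroc = wins / (len(pos) * len(neg))

    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(probs), reverse=True):
        sel = probs >= thr
        precision = labels[sel].sum() / sel.sum()
        recall = labels[sel].sum() / labels.sum()
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return acc, auroc, ap, f1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_metrics_agree_with_brute_force(data):
    n = data.draw(st.integers(4, 20))
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(labels)) < 2:
        labels[0], labels[-1] = 0, 1
    # quantized scores force ties to exercise the tie-handling paths
    probs = data.draw(st.lists(
        st.integers(0, 10).map(lambda k: k / 10), min_size=n, max_size=n))
    report = evaluate(np.array(probs), np.array(labels))
    acc, auroc, ap, f1 = brute_force_metrics(probs, labels)
    assert report.acc == pytest.approx(acc, abs=1e-12)
    assert report.auroc == pytest.approx(auroc, abs=1e-12)
    assert report.auprc == pytest.approx(ap, abs=1e-9)
    assert report.f1 == pytest.approx(f1, abs=1e-12)


def test_perfect_and_inverted_ranking():
    report = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
    assert (report.acc, report.auroc, report.auprc, report.f1) == (1, 1, 1, 1)
    inverted = evaluate(np.array([0.9, 0.1]), np.array([0, 1]))
    assert inverted.auroc == 0.0


def test_single_class_reports_nan_with_warning():
    with pytest.warns(UserWarning, match="one class"):
        report = evaluate(np.array([0.2, 0.9]), np.array([1, 1]))
    assert np.isnan(report.auroc) and np.isnan(report.auprc)


def test_config_rejects_non_unit_negative_ratio():
    with pytest.raises(ValueError, match="1:1"):
        TrainConfig(neg_ratio=2)


def test_split_spec_validates_fractions():
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=0.5, val_fraction=0.2, test_fraction=0.2)
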