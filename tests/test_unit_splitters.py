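"""Rule-based splitters, boundary evaluation, and the pointer network."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granusum.corpus_core import SentenceRecord, Token, enumerate_units, Document
from granusum.unit_splitters import (
    PointerConfig,
    PointerSplitterModel,
    evaluate_boundaries,
    split_clauses_pos,
    split_fullstop,
    split_fullstop_verb,
    train_pointer_splitter,
)

from conftest import make_sentence

POS_CHOICES = ("noun", "noun_nonindependent", "verb", "particle", "fullstop", "comma", "other")


def pos_sentence(pos_seq):
    return SentenceRecord(tokens=[Token(f"w{i}", p) for i, p in enumerate(pos_seq)])


def brute_fullstop(pos_seq):
    return {i + 1 for i, p in enumerate(pos_seq) if p == "fullstop" and i + 1 < len(pos_seq)}


def brute_fullstop_verb(pos_seq):
    out = brute_fullstop(pos_seq)
    for i, p in enumerate(pos_seq):
        if p != "verb":
            continue
        j = i + 1
        while j < len(pos_seq) and pos_seq[j] != "noun":
            j += 1
        if j < len(pos_seq):
            out.add(j)
    return {b for b in out if 0 < b < len(pos_seq)}


def brute_clause(pos_seq):
    return {
        i + 1
        for i, p in enumerate(pos_seq)
        if p in ("particle", "verb") and i + 1 < len(pos_seq)
    }


class TestRuleSplitters:
    def test_no_fullstops_empty(self):
        assert split_fullstop(pos_sentence(["noun", "verb"])) == set()

    def test_final_fullstop_excluded(self):
        pos = ["noun", "noun", "noun", "fullstop", "noun", "fullstop"]
        assert split_fullstop(pos_sentence(pos)) == {4}

    def test_verb_then_next_independent_noun(self):
        pos = ["verb", "particle", "noun_nonindependent", "noun", "other"]
        assert split_fullstop_verb(pos_sentence(pos)) == {3}

    def test_verb_with_no_following_noun(self):
        assert split_fullstop_verb(pos_sentence(["noun", "verb", "particle"])) == set()

    def test_clause_splitter_after_particles_and_verbs(self):
        pos = ["noun", "particle", "noun", "verb", "noun"]
        assert split_clauses_pos(pos_sentence(pos)) == {2, 4}

    @given(st.lists(st.sampled_from(POS_CHOICES), min_size=1, max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_match_brute_force_rules(self, pos_seq):
        sent = pos_sentence(pos_seq)
        assert split_fullstop(sent) == brute_fullstop(pos_seq)
        assert split_fullstop_verb(sent) == brute_fullstop_verb(pos_seq)
        assert split_clauses_pos(sent) == brute_clause(pos_seq)

    @given(st.lists(st.sampled_from(POS_CHOICES), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_outputs_partition_sentence(self, pos_seq):
        sent = pos_sentence(pos_seq)
        for splitter in (split_fullstop, split_fullstop_verb, split_clauses_pos):
            bounds = sorted(splitter(sent))
            assert all(0 < b < len(pos_seq) for b in bounds)
            units = enumerate_units(Document("d", [sent]), "segment", [bounds])
            assert units[0].start == 0 and units[-1].end == len(pos_seq)


class TestEvaluateBoundaries:
    def test_perfect_prediction(self):
        ev = evaluate_boundaries([{1, 2}], [{1, 2}])
        assert (ev.precision, ev.recall, ev.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_zero_recall(self):
        ev = evaluate_boundaries([set()], [{1}])
        assert ev.recall == 0.0 and ev.f1 == 0.0

    def test_hand_counted_micro_average(self):
        # TP=2, FP=1, FN=1 across two sentences
        ev = evaluate_boundaries([{1, 3}, {2}], [{1, 2}, {2}])
        assert (ev.tp, ev.fp, ev.fn) == (2, 1, 1)
        assert ev.precision == pytest.approx(2 / 3)
        assert ev.recall == pytest.approx(2 / 3)
        assert ev.f1 == pytest.approx(2 / 3)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            evaluate_boundaries([set()], [set(), set()])


@pytest.fixture(scope="module")
def trained_pointer(small_corpus):
    sents = [s for p in small_corpus for s in p.source.sentences]
    cfg = PointerConfig(seed=5, epochs=5, hidden_size=16, embed_dim=16)
    model, log = train_pointer_splitter(sents[:220], sents[220:260], cfg)
    return model, log, sents


class TestPointerSplitter:
    def test_empty_training_set_is_error(self):
        with pytest.raises(ValueError):
            train_pointer_splitter([], [], PointerConfig(seed=1))

    def test_one_token_sentence_no_boundaries(self, trained_pointer):
        model, _, _ = trained_pointer
        assert model.predict(make_sentence("a/noun")) == set()

    def test_predictions_strictly_internal_and_increasing(self, trained_pointer):
        model, _, sents = trained_pointer
        for s in sents[260:300]:
            bounds = sorted(model.predict(s))
            assert all(0 < b < len(s.tokens) for b in bounds)
            assert bounds == sorted(set(bounds))

    def test_learns_cue_rule_on_held_out_sentences(self, trained_pointer):
        model, log, sents = trained_pointer
        gold = [set(s.gold_segment_boundaries) for s in sents[260:340]]
        pred = [model.predict(s) for s in sents[260:340]]
        assert evaluate_boundaries(pred, gold).f1 >= 0.9
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_training_determinism(self, small_corpus):
        sents = [s for p in small_corpus[:6] for s in p.source.sentences]
        cfg = PointerConfig(seed=9, epochs=2, hidden_size=8, embed_dim=8)
        m1, _ = train_pointer_splitter(sents[:40], sents[40:48], cfg)
        m2, _ = train_pointer_splitter(sents[:40], sents[40:48], cfg)
        for s in sents[48:60]:
            assert m1.predict(s) == m2.predict(s)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_unknown_surfaces_get_ngram_embeddings(self, trained_pointer):
        model, _, _ = trained_pointer
        sent = make_sentence("zzzzq/noun qqqqz/verb xxxxj/noun wwwwk/verb")
        bounds = model.predict(sent)  # must not fail on unseen words
        assert all(0 < b < 4 for b in bounds)

    def test_save_load_identical_predictions(self, trained_pointer, tmp_path):
        model, _, sents = trained_pointer
        path = tmp_path / "pointer.npz"
        model.save(path)
        loaded = PointerSplitterModel.load(path)
        for s in sents[300:320]:
            assert loaded.predict(s) == model.predict(s)


class TestSixFoldOrdering:
    def test_cross_validated_pointer_beats_rule_baselines(self, small_corpus):
        """Six-fold cross-validation: the learned splitter dominates the
        full-stop rules whenever boundaries are cue-driven."""
        sents = [s for p in small_corpus[:18] for s in p.source.sentences]
        folds = np.array_split(np.arange(len(sents)), 6)
        pointer_f1 = fs_f1 = fsv_f1 = 0.0
        for fold in folds[:2]:  # two folds keep the runtime modest
            test_idx = set(fold.tolist())
            train = [s for i, s in enumerate(sents) if i not in test_idx]
            test = [s for i, s in enumerate(sents) if i in test_idx]
            cfg = PointerConfig(seed=3, epochs=4, hidden_size=16, embed_dim=16)
            model, _ = train_pointer_splitter(train, test, cfg)
            gold = [set(s.gold_segment_boundaries) for s in test]
            pointer_f1 += evaluate_boundaries([model.predict(s) for s in test], gold).f1
            fs_f1 += evaluate_boundaries([split_fullstop(s) for s in test], gold).f1
            fsv_f1 += evaluate_boundaries([split_fullstop_verb(s) for s in test], gold).f1
        assert pointer_f1 > fsv_f1 > fs_f1
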