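"""Unit encoding, scoring, budgeted inference, training, and ROUGE reporting."""

from __future__ import annotations

import numpy as np
import pytest

from granusum.corpus_core import Document, Unit, enumerate_units
from granusum.extractive_summarizer import (
    SummarizerConfig,
    SummarizerModel,
    build_token_vocab,
    evaluate_summaries,
    predict_summary,
    train_summarizer,
)
from granusum.oracle_labeling import label_document

from conftest import make_sentence


def unit(i, a, b, gran="segment", chars=None):
    return Unit(
        sentence_index=i, start=a, end=b, granularity=gran,
        char_len=chars if chars is not None else b - a,
    )


@pytest.fixture
def toy_doc():
    return Document(
        "d",
        [
            make_sentence("aa/noun bb/particle cc/verb", seg=(2,)),
            make_sentence("dd/noun ee/verb"),
        ],
    )


def tiny_model(doc, seed=0, **kw):
    cfg = SummarizerConfig(seed=seed, hidden=16, ffn_dim=16, epochs=1, **kw)
    return SummarizerModel(cfg, build_token_vocab([doc]))


class TestEncodeUnits:
    def test_single_token_unit_equals_token_vector(self, toy_doc):
        model = tiny_model(toy_doc)
        token_mat, offsets = model._encode_tokens(toy_doc)
        enc = model.encode_units(toy_doc, [unit(0, 2, 3)])
        cls_row, tok0 = offsets[0]
        assert np.allclose(enc.data[0], token_mat.data[tok0 + 2])

    def test_multi_token_unit_is_mean_of_member_vectors(self, toy_doc):
        model = tiny_model(toy_doc)
        token_mat, offsets = model._encode_tokens(toy_doc)
        enc = model.encode_units(toy_doc, [unit(0, 0, 3)])
        _, tok0 = offsets[0]
        manual = token_mat.data[tok0 : tok0 + 3].mean(axis=0)
        assert np.allclose(enc.data[0], manual)

    def test_sentence_granularity_uses_cls_vector(self, toy_doc):
        model = tiny_model(toy_doc)
        token_mat, offsets = model._encode_tokens(toy_doc)
        enc = model.encode_units(toy_doc, [unit(1, 0, 2, gran="sentence")])
        cls_row, _ = offsets[1]
        assert np.allclose(enc.data[0], token_mat.data[cls_row])

    def test_chunking_covers_long_documents(self):
        doc = Document(
            "d", [make_sentence("aa/noun bb/verb cc/noun") for _ in range(30)]
        )
        model = tiny_model(doc, max_window=20)
        assert len(model._chunks(doc)) > 1
        probs = model.score_units(doc, enumerate_units(doc, "sentence"))
        assert probs.shape == (30,)


class TestScoring:
    def test_zero_output_weights_give_half(self, toy_doc):
        model = tiny_model(toy_doc)
        model.params["Wout"].data[:] = 0.0
        model.params["bout"].data[:] = 0.0
        probs = model.score_units(toy_doc, enumerate_units(toy_doc, "sentence"))
        assert np.allclose(probs, 0.5)

    def test_hand_computed_sigmoid_head(self, toy_doc):
        model = tiny_model(toy_doc)
        units = enumerate_units(toy_doc, "segment")
        enc = model.encode_units(toy_doc, units)
        logits = model.unit_logits(enc)
        probs = model.score_units(toy_doc, units)
        assert np.allclose(probs, 1 / (1 + np.exp(-logits.data)))

    def test_identical_units_get_identical_scores_without_positions(self, toy_doc):
        # two copies of the same sentence: with positional encodings disabled
        # the unit-level layer is permutation-equivariant
        doc = Document(
            "d",
            [
                make_sentence("aa/noun bb/verb"),
                make_sentence("aa/noun bb/verb"),
            ],
        )
        model = tiny_model(doc, positional_encodings=False)
        probs = model.score_units(doc, enumerate_units(doc, "sentence"))
        assert probs[0] == pytest.approx(probs[1])

    def test_permutation_equivariance_without_positions(self):
        s1 = make_sentence("aa/noun bb/verb")
        s2 = make_sentence("cc/noun dd/verb")
        doc_a = Document("d", [s1, s2])
        doc_b = Document("d", [s2, s1])
        cfg = SummarizerConfig(seed=1, hidden=16, ffn_dim=16, positional_encodings=False)
        vocab = build_token_vocab([doc_a])
        model_a = SummarizerModel(cfg, vocab)
        pa = model_a.score_units(doc_a, enumerate_units(doc_a, "sentence"))
        pb = model_a.score_units(doc_b, enumerate_units(doc_b, "sentence"))
        assert np.allclose(pa, pb[::-1])


class TestPredictSummary:
    class _Fixed:
        """Stand-in model returning preset probabilities."""

        def __init__(self, probs):
            self._probs = np.asarray(probs)

        def score_units(self, doc, units):
            return self._probs

    def test_budget_covers_everything(self, toy_doc):
        units = enumerate_units(toy_doc, "segment")
        model = self._Fixed([0.2, 0.9, 0.4])
        selected, text = predict_summary(model, toy_doc, units, budget_chars=10_000)
        assert selected == units
        assert text == "aabbccddee"

    def test_dominant_unit_tiny_budget(self, toy_doc):
        units = enumerate_units(toy_doc, "segment")
        model = self._Fixed([0.05, 0.9, 0.1])
        selected, text = predict_summary(model, toy_doc, units, budget_chars=1)
        assert [u.start for u in selected] == [2]
        assert text == "cc"

    def test_trace_with_fixed_probabilities(self, toy_doc):
        units = enumerate_units(toy_doc, "segment")  # char lens 4, 2, 4
        model = self._Fixed([0.9, 0.8, 0.1])
        selected, _ = predict_summary(model, toy_doc, units, budget_chars=5)
        # 0.9-unit (4 chars) fits; 0.8-unit overflows (6 > 5): included, stop
        assert [(u.sentence_index, u.start) for u in selected] == [(0, 0), (0, 2)]

    def test_output_in_document_order(self, toy_doc):
        units = enumerate_units(toy_doc, "segment")
        model = self._Fixed([0.1, 0.5, 0.9])
        selected, _ = predict_summary(model, toy_doc, units, budget_chars=10)
        order = [(u.sentence_index, u.start) for u in selected]
        assert order == sorted(order)


class TestEvaluateSummaries:
    def test_identity_scores_hundred(self):
        docs = [[["a", "b"], ["c", "d"]]]
        out = evaluate_summaries(docs, docs)
        assert out == {"rouge1": 100.0, "rouge2": 100.0, "rougeL": 100.0}

    def test_disjoint_scores_zero(self):
        out = evaluate_summaries([[["a", "b"]]], [[["x", "y"]]])
        assert out == {"rouge1": 0.0, "rouge2": 0.0, "rougeL": 0.0}

    def test_two_document_mean_by_hand(self):
        preds = [[["a", "b"]], [["x", "y"]]]
        refs = [[["a", "b"]], [["x", "z"]]]
        out = evaluate_summaries(preds, refs)
        assert out["rouge1"] == pytest.approx((100.0 + 50.0) / 2)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            evaluate_summaries([], [])


class TestTraining:
    def _marker_dataset(self, n_docs, seed):
        """Documents where copy-worthy units carry a marker token; references
        repeat those units, making the labels linearly separable."""
        from granusum.corpus_core import DocumentPair

        rng = np.random.default_rng(seed)
        data = []
        for d in range(n_docs):
            sents, ref_sents = [], []
            for i in range(4):
                good = bool(rng.integers(0, 2)) or i == 0
                word = f"w{rng.integers(0, 30)}"
                if good:
                    sents.append(make_sentence(f"mk/noun {word}/noun yy/verb"))
                    ref_sents.append(make_sentence(f"mk/noun {word}/noun yy/verb"))
                else:
                    sents.append(make_sentence(f"zz/noun {word}/noun qq/verb"))
            pair = DocumentPair(
                Document(f"d{d}", sents), Document(f"d{d}", ref_sents)
            )
            units = enumerate_units(pair.source, "sentence")
            labeled = label_document(pair, units, budget_chars=10_000)
            data.append((pair, labeled.units))
        return data

    def test_planted_marker_recovery(self):
        train = self._marker_dataset(24, seed=1)
        dev = self._marker_dataset(6, seed=2)
        cfg = SummarizerConfig(seed=3, hidden=16, ffn_dim=32, epochs=6, learning_rate=5e-3)
        model, log = train_summarizer(train, dev, cfg, budget_chars=10_000)
        losses = [e["train_loss"] for e in log]
        assert losses[-1] < losses[0] * 0.5
        # held-out discrimination: marker units must outscore non-marker units
        test = self._marker_dataset(8, seed=4)
        correct = total = 0
        for pair, labeled in test:
            probs = model.score_units(pair.source, [lu.unit for lu in labeled])
            for p, lu in zip(probs, labeled):
                total += 1
                correct += int((p > 0.5) == bool(lu.label))
        assert correct / total >= 0.9

    def test_training_determinism(self):
        train = self._marker_dataset(6, seed=1)
        cfg = SummarizerConfig(seed=5, hidden=8, ffn_dim=8, epochs=2)
        m1, _ = train_summarizer(train, [], cfg, budget_chars=100)
        m2, _ = train_summarizer(train, [], cfg, budget_chars=100)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_empty_training_set_is_error(self):
        with pytest.raises(ValueError):
            train_summarizer([], [], SummarizerConfig(seed=1), budget_chars=10)

    def test_save_load_identical_scores(self, toy_doc, tmp_path):
        model = tiny_model(toy_doc)
        units = enumerate_units(toy_doc, "segment")
        path = tmp_path / "summ.npz"
        model.save(path)
        loaded = SummarizerModel.load(path)
        assert np.allclose(
            loaded.score_units(toy_doc, units), model.score_units(toy_doc, units)
        )


class TestOracleCeilingHarness:
    def test_oracle_probabilities_reproduce_oracle_summary(self, toy_doc):
        # with p = y and a non-binding budget, greedy selection returns
        # exactly the positively labeled units
        units = enumerate_units(toy_doc, "segment")
        labels = [1.0, 0.0, 1.0]
        model = TestPredictSummary._Fixed(labels)
        selected, _ = predict_summary(model, toy_doc, units, budget_chars=8)
        assert [(u.sentence_index, u.start) for u in selected] == [(0, 0), (1, 0)]
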