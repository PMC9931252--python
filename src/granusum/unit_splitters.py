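"""Segment splitters: rule-based baselines and a pointer-network model.

Four ways of placing internal boundaries inside a tokenized sentence:

* ``split_fullstop`` — boundary after every non-final full-stop token.
* ``split_fullstop_verb`` — additionally, for every verb, a boundary in
  front of the next independent noun (non-independent nouns are skipped).
* ``split_clauses_pos`` — a clause-style splitter: boundary after every
  particle and every verb.  This plays the role of a hand-built clause
  grammar; it deliberately over-splits relative to segment boundaries.
* a trainable pointer network: a bidirectional recurrent encoder over
  fastText-style embeddings (word vector plus hashed character 3–5-gram
  vectors, so unknown surfaces still get a representation, plus a
  part-of-speech embedding — the corpus is morphologically tagged upstream),
  and a recurrent
  decoder that, starting at token 0, repeatedly points to the end position
  of the current unit among the remaining positions.  Decoding is strictly
  monotone and terminates at the sentence end; pointer-score ties break
  toward the earliest position.

Boundary evaluation is exact-position precision/recall/F1, micro-averaged
over sentences.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import Tensor
from .corpus_core import POS_TAGS, SentenceRecord

UNK_ID = 0  # row 0 of the word table backs surfaces outside the vocabulary

_POS_INDEX = {tag: i for i, tag in enumerate(sorted(POS_TAGS))}


# ---------------------------------------------------------------------------
# rule-based splitters


def split_fullstop(sentence: SentenceRecord) -> set[int]:
    """Boundary after every full-stop token that is not sentence-final."""
    n = len(sentence.tokens)
    return {
        i + 1
        for i, tok in enumerate(sentence.tokens)
        if tok.pos == "fullstop" and 0 < i + 1 < n
    }


def split_fullstop_verb(sentence: SentenceRecord) -> set[int]:
    """Full-stop boundaries plus a boundary before the next independent noun
    after each verb."""
    bounds = split_fullstop(sentence)
    tokens = sentence.tokens
    n = len(tokens)
    for i, tok in enumerate(tokens):
        if tok.pos != "verb":
            continue
        for j in range(i + 1, n):
            if tokens[j].pos == "noun":
                if 0 < j < n:
                    bounds.add(j)
                break
    return bounds


def split_clauses_pos(sentence: SentenceRecord) -> set[int]:
    """Clause-style splitting: boundary after every particle and every verb."""
    n = len(sentence.tokens)
    return {
        i + 1
        for i, tok in enumerate(sentence.tokens)
        if tok.pos in ("particle", "verb") and 0 < i + 1 < n
    }


# ---------------------------------------------------------------------------
# boundary evaluation


@dataclass(frozen=True)
class BoundaryEval:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def evaluate_boundaries(
    predicted: Sequence[set[int]], gold: Sequence[set[int]]
) -> BoundaryEval:
    """Micro-averaged exact-position boundary precision/recall/F1."""
    if len(predicted) != len(gold):
        raise ValueError(
            f"sentence count mismatch: {len(predicted)} predicted vs {len(gold)} gold"
        )
    tp = fp = fn = 0
    for pred, ref in zip(predicted, gold):
        pred = set(pred)
        ref = set(ref)
        tp += len(pred & ref)
        fp += len(pred - ref)
        fn += len(ref - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return BoundaryEval(precision, recall, f1, tp, fp, fn)


# ---------------------------------------------------------------------------
# pointer network


@dataclass(frozen=True)
class PointerConfig:
    seed: int
    embed_dim: int = 32
    hidden_size: int = 64  # per direction
    ngram_buckets: int = 2048
    ngram_min: int = 3
    ngram_max: int = 5
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 5e-3


def _char_ngram_ids(surface: str, cfg_min: int, cfg_max: int, buckets: int) -> list[int]:
    padded = f"<{surface}>"
    ids = []
    for n in range(cfg_min, cfg_max + 1):
        for i in range(len(padded) - n + 1):
            ids.append(zlib.crc32(padded[i : i + n].encode("utf-8")) % buckets)
    return ids


class PointerSplitterModel:
    """Pointer-network segment splitter (encoder, decoder, pointer scorer)."""

    def __init__(self, config: PointerConfig, vocab: dict[str, int], params=None):
        self.config = config
        self.vocab = vocab
        if params is None:
            rng = np.random.default_rng(config.seed)
            d, h = config.embed_dim, config.hidden_size
            g = lambda *shape: Tensor(_nn.glorot(rng, shape))
            self.params: dict[str, Tensor] = {
                "word_emb": Tensor(rng.normal(0.0, 0.1, size=(len(vocab) + 1, d))),
                "ngram_emb": Tensor(rng.normal(0.0, 0.1, size=(config.ngram_buckets, d))),
                "pos_emb": Tensor(rng.normal(0.0, 0.1, size=(len(_POS_INDEX), d))),
                "Wf": g(d, h), "Uf": g(h, h), "bf": Tensor(np.zeros(h)),
                "Wb": g(d, h), "Ub": g(h, h), "bb": Tensor(np.zeros(h)),
                "Wd": g(2 * h, h), "Ud": g(h, h), "bd": Tensor(np.zeros(h)),
                "Wp": g(2 * h, h), "Wq": g(h, h), "bp": Tensor(np.zeros(h)),
                "v": g(h, 1),
            }
        else:
            self.params = params

    # -- embedding ----------------------------------------------------------

    def _token_vectors(self, sentence: SentenceRecord) -> Tensor:
        cfg = self.config
        surfaces = [t.surface for t in sentence.tokens]
        word_ids = np.array([self.vocab.get(s, UNK_ID) for s in surfaces], dtype=np.intp)
        word_part = _nn.take_rows(self.params["word_emb"], word_ids)  # (T, d)
        pos_ids = np.array(
            [_POS_INDEX.get(t.pos, _POS_INDEX["other"]) for t in sentence.tokens],
            dtype=np.intp,
        )
        pos_part = _nn.take_rows(self.params["pos_emb"], pos_ids)
        ngram_means = []
        for surface in surfaces:
            ng = _char_ngram_ids(surface, cfg.ngram_min, cfg.ngram_max, cfg.ngram_buckets)
            if ng:
                ngram_means.append(
                    _nn.tmean(
                        _nn.take_rows(self.params["ngram_emb"], np.array(ng, dtype=np.intp)),
                        axis=0,
                    )
                )
            else:
                ngram_means.append(Tensor(np.zeros(cfg.embed_dim)))
        return word_part + pos_part + _nn.stack_rows(ngram_means)  # (T, d)

    # -- encoder ------------------------------------------------------------

    def _encode(self, sentence: SentenceRecord) -> Tensor:
        p = self.params
        x = self._token_vectors(sentence)
        T = len(sentence.tokens)
        h = self.config.hidden_size
        fwd: list[Tensor] = []
        state = Tensor(np.zeros((1, h)))
        for t in range(T):
            state = _nn.tanh(x[t : t + 1] @ p["Wf"] + state @ p["Uf"] + p["bf"])
            fwd.append(state)
        bwd: list[Tensor] = [None] * T  # type: ignore[list-item]
        state = Tensor(np.zeros((1, h)))
        for t in range(T - 1, -1, -1):
            state = _nn.tanh(x[t : t + 1] @ p["Wb"] + state @ p["Ub"] + p["bb"])
            bwd[t] = state
        rows = [_nn.concat([fwd[t], bwd[t]], axis=1) for t in range(T)]
        return _nn.concat(rows, axis=0)  # (T, 2h)

    def _pointer_scores(self, H: Tensor, dec_state: Tensor, candidates: Sequence[int]) -> Tensor:
        """Scores over candidate boundary positions; position j is represented
        by the encoding of token j-1, the last token of the would-be unit."""
        p = self.params
        idx = np.array([j - 1 for j in candidates], dtype=np.intp)
        Hc = H[idx]  # (C, 2h)
        mix = _nn.tanh(Hc @ p["Wp"] + dec_state @ p["Wq"] + p["bp"])
        return _nn.reshape(mix @ p["v"], (len(candidates),))

    def _sentence_loss(self, sentence: SentenceRecord) -> Tensor | None:
        T = len(sentence.tokens)
        if T < 2:
            return None
        H = self._encode(sentence)
        h = self.config.hidden_size
        p = self.params
        bounds = list(sentence.gold_segment_boundaries) + [T]
        start = 0
        dec_state = Tensor(np.zeros((1, h)))
        losses: list[Tensor] = []
        for end in bounds:
            dec_state = _nn.tanh(
                H[start : start + 1] @ p["Wd"] + dec_state @ p["Ud"] + p["bd"]
            )
            candidates = list(range(start + 1, T + 1))
            scores = self._pointer_scores(H, dec_state, candidates)
            losses.append(_nn.cross_entropy_logits(scores, candidates.index(end)))
            start = end
        total = losses[0]
        for loss in losses[1:]:
            total = total + loss
        return total * Tensor(1.0 / len(losses))

    # -- public API ---------------------------------------------------------

    def predict(self, sentence: SentenceRecord) -> set[int]:
        """Greedy monotone decode; returns the internal boundary set."""
        T = len(sentence.tokens)
        if T < 2:
            return set()
        H = self._encode(sentence)
        h = self.config.hidden_size
        p = self.params
        bounds: set[int] = set()
        start = 0
        dec_state = Tensor(np.zeros((1, h)))
        while start < T:
            dec_state = _nn.tanh(
                H[start : start + 1] @ p["Wd"] + dec_state @ p["Ud"] + p["bd"]
            )
            candidates = list(range(start + 1, T + 1))
            scores = self._pointer_scores(H, dec_state, candidates)
            end = candidates[int(np.argmax(scores.data))]  # first max: earliest tie-break
            if end < T:
                bounds.add(end)
            start = end
        return bounds

    def save(self, path) -> None:
        meta = {
            "config": self.config.__dict__,
            "vocab": self.vocab,
        }
        _nn.save_params(path, self.params, meta)

    @classmethod
    def load(cls, path) -> "PointerSplitterModel":
        params, meta = _nn.load_params(path)
        return cls(PointerConfig(**meta["config"]), meta["vocab"], params=params)


def build_vocab(sentences: Sequence[SentenceRecord]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for sent in sentences:
        for tok in sent.tokens:
            if tok.surface not in vocab:
                vocab[tok.surface] = len(vocab) + 1  # 0 reserved for UNK
    return vocab


def train_pointer_splitter(
    train: Sequence[SentenceRecord],
    dev: Sequence[SentenceRecord],
    config: PointerConfig,
) -> tuple[PointerSplitterModel, list[dict]]:
    """Train by teacher-forced pointer cross-entropy; return the best-dev model.

    The returned log has one entry per epoch with the mean training loss and
    the dev boundary F1.
    """
    if not train:
        raise ValueError("empty training set")
    model = PointerSplitterModel(config, build_vocab(train))
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    best_f1 = -1.0
    best_params: dict[str, Tensor] | None = None
    gold_dev = [set(s.gold_segment_boundaries) for s in dev]
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[b0 : b0 + config.batch_size]]
            losses = [l for l in (model._sentence_loss(s) for s in batch) if l is not None]
            if not losses:
                continue
            total = losses[0]
            for loss in losses[1:]:
                total = total + loss
            total = total * Tensor(1.0 / len(losses))
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
            n_batches += 1
        if dev:
            pred_dev = [model.predict(s) for s in dev]
            dev_f1 = evaluate_boundaries(pred_dev, gold_dev).f1
        else:
            dev_f1 = 0.0
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "dev_f1": dev_f1,
            }
        )
        if dev_f1 > best_f1:
            best_f1 = dev_f1
            best_params = {k: Tensor(p.data.copy()) for k, p in model.params.items()}
    if best_params is not None and dev:
        model.params = best_params
    return model, log


def predict_boundaries(model: PointerSplitterModel, sentence: SentenceRecord) -> set[int]:
    return model.predict(sentence)
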