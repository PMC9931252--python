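"""Unit-level extractive summarization model.

One architecture covers all three granularities.  Tokens of each sentence,
wrapped in begin-of-sentence ([CLS]) and separator ([SEP]) markers, are
encoded by a small trainable self-attention stack (a pluggable stand-in for
a pretrained clinical masked-LM encoder).  A unit representation s'_{i,j} is
the arithmetic mean of its member-token vectors — [CLS]/[SEP] excluded — for
segment and clause units, and the sentence's [CLS] vector for sentence units
(no pooling).  A unit-level transformer layer then contextualizes the unit
sequence of the whole document, and each contextualized unit s''_{i,j} is
scored p = sigmoid(W_o s'' + b_o).  Training minimizes mean binary
cross-entropy against the oracle labels y_{i,j}.

Inference ranks units by predicted probability (ties broken by document
order) and selects greedily under the same include-then-stop character
budget used for labeling; the selection is re-sorted to document order.

Overlong documents are chunked at sentence boundaries into windows of at
most ``max_window`` tokens for the token encoder; the unit-level attention
still sees the whole document.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import Tensor
from .corpus_core import Document, DocumentPair, Unit
from .oracle_labeling import LabeledUnit, assign_labels
from .rouge_metrics import rouge_l, rouge_n

CLS, SEP, UNK = "[CLS]", "[SEP]", "[UNK]"


@dataclass(frozen=True)
class SummarizerConfig:
    seed: int
    hidden: int = 64
    token_layers: int = 2
    heads: int = 2
    ffn_dim: int = 128
    max_window: int = 512
    epochs: int = 5
    batch_docs: int = 8
    learning_rate: float = 5e-3
    positional_encodings: bool = True


def build_token_vocab(docs: Sequence[Document]) -> dict[str, int]:
    vocab = {UNK: 0, CLS: 1, SEP: 2}
    for doc in docs:
        for surface in doc.surface_stream():
            if surface not in vocab:
                vocab[surface] = len(vocab)
    return vocab


def _transformer_layer(x: Tensor, p: dict[str, Tensor], prefix: str, heads: int) -> Tensor:
    """Pre-built post-norm transformer block over a (T, d) tensor."""
    d = x.shape[1]
    dh = d // heads
    q = x @ p[f"{prefix}Wq"]
    k = x @ p[f"{prefix}Wk"]
    v = x @ p[f"{prefix}Wv"]
    head_outs = []
    scale = Tensor(1.0 / np.sqrt(dh))
    for hi in range(heads):
        sl = slice(hi * dh, (hi + 1) * dh)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        attn = _nn.softmax(_nn.mul(qh @ _nn.transpose(kh), scale), axis=-1)
        head_outs.append(attn @ vh)
    mha = _nn.concat(head_outs, axis=1) @ p[f"{prefix}Wo"]
    y = _nn.layer_norm(x + mha, p[f"{prefix}ln1_g"], p[f"{prefix}ln1_b"])
    ffn = _nn.relu(y @ p[f"{prefix}W1"] + p[f"{prefix}b1"]) @ p[f"{prefix}W2"] + p[f"{prefix}b2"]
    return _nn.layer_norm(y + ffn, p[f"{prefix}ln2_g"], p[f"{prefix}ln2_b"])


def _init_transformer_layer(rng, params: dict[str, Tensor], prefix: str, d: int, ffn: int) -> None:
    g = lambda *shape: Tensor(_nn.glorot(rng, shape))
    params[f"{prefix}Wq"] = g(d, d)
    params[f"{prefix}Wk"] = g(d, d)
    params[f"{prefix}Wv"] = g(d, d)
    params[f"{prefix}Wo"] = g(d, d)
    params[f"{prefix}W1"] = g(d, ffn)
    params[f"{prefix}b1"] = Tensor(np.zeros(ffn))
    params[f"{prefix}W2"] = g(ffn, d)
    params[f"{prefix}b2"] = Tensor(np.zeros(d))
    params[f"{prefix}ln1_g"] = Tensor(np.ones(d))
    params[f"{prefix}ln1_b"] = Tensor(np.zeros(d))
    params[f"{prefix}ln2_g"] = Tensor(np.ones(d))
    params[f"{prefix}ln2_b"] = Tensor(np.zeros(d))


class SummarizerModel:
    """Token encoder + unit pooling + unit-level transformer + sigmoid head."""

    def __init__(self, config: SummarizerConfig, vocab: dict[str, int], params=None):
        self.config = config
        self.vocab = vocab
        if params is not None:
            self.params = params
            return
        rng = np.random.default_rng(config.seed)
        d = config.hidden
        self.params = {
            "emb": Tensor(rng.normal(0.0, 0.1, size=(len(vocab), d))),
        }
        for layer in range(config.token_layers):
            _init_transformer_layer(rng, self.params, f"tok{layer}_", d, config.ffn_dim)
        _init_transformer_layer(rng, self.params, "unit_", d, config.ffn_dim)
        self.params["Wout"] = Tensor(_nn.glorot(rng, (d, 1)))
        self.params["bout"] = Tensor(np.zeros(1))

    # -- encoding -----------------------------------------------------------

    def _chunks(self, doc: Document) -> list[list[int]]:
        """Group sentence indices into windows of at most max_window tokens
        (each sentence contributes len + 2 marker tokens)."""
        chunks: list[list[int]] = []
        current: list[int] = []
        count = 0
        for i, sent in enumerate(doc.sentences):
            need = len(sent.tokens) + 2
            if current and count + need > self.config.max_window:
                chunks.append(current)
                current = []
                count = 0
            current.append(i)
            count += need
        if current:
            chunks.append(current)
        return chunks

    def _encode_tokens(self, doc: Document) -> tuple[Tensor, dict[int, tuple[int, int]]]:
        """Run the token encoder; returns the stacked (N, d) token matrix over
        all chunks plus, per sentence, the (cls_row, first_token_row) offsets."""
        cfg = self.config
        chunk_outs: list[Tensor] = []
        offsets: dict[int, tuple[int, int]] = {}
        row_base = 0
        for chunk in self._chunks(doc):
            ids: list[int] = []
            for i in chunk:
                offsets[i] = (row_base + len(ids), row_base + len(ids) + 1)
                ids.append(self.vocab[CLS])
                ids.extend(self.vocab.get(t.surface, 0) for t in doc.sentences[i].tokens)
                ids.append(self.vocab[SEP])
            x = _nn.take_rows(self.params["emb"], np.array(ids, dtype=np.intp))
            if cfg.positional_encodings:
                # positions are scaled to the embedding-init magnitude so the
                # lexical signal is not drowned at initialization
                x = x + Tensor(0.1 * _nn.sinusoidal_positions(len(ids), cfg.hidden))
            for layer in range(cfg.token_layers):
                x = _transformer_layer(x, self.params, f"tok{layer}_", cfg.heads)
            chunk_outs.append(x)
            row_base += len(ids)
        return _nn.concat(chunk_outs, axis=0), offsets

    def encode_units(self, doc: Document, units: Sequence[Unit]) -> Tensor:
        """Per-unit vectors: mean-pooled member tokens, or the [CLS] vector
        for sentence-granularity units."""
        token_mat, offsets = self._encode_tokens(doc)
        rows: list[Tensor] = []
        for u in units:
            if u.end <= u.start:
                raise ValueError(f"empty unit {u}")
            cls_row, tok0 = offsets[u.sentence_index]
            if u.granularity == "sentence":
                rows.append(_nn.reshape(token_mat[cls_row : cls_row + 1], (self.config.hidden,)))
            else:
                span = token_mat[tok0 + u.start : tok0 + u.end]
                rows.append(_nn.tmean(span, axis=0))
        return _nn.stack_rows(rows)  # (U, d)

    def unit_logits(self, encodings: Tensor) -> Tensor:
        """Unit-level self-attention followed by the affine scoring head."""
        cfg = self.config
        x = encodings
        if cfg.positional_encodings:
            x = x + Tensor(0.1 * _nn.sinusoidal_positions(x.shape[0], cfg.hidden))
        x = _transformer_layer(x, self.params, "unit_", cfg.heads)
        return _nn.reshape(x @ self.params["Wout"] + self.params["bout"], (x.shape[0],))

    def score_units(self, doc: Document, units: Sequence[Unit]) -> np.ndarray:
        """Predicted extraction probabilities for each unit."""
        if not units:
            raise ValueError("no units to score")
        logits = self.unit_logits(self.encode_units(doc, units))
        return 1.0 / (1.0 + np.exp(-logits.data))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        _nn.save_params(path, self.params, {"config": asdict(self.config), "vocab": self.vocab})

    @classmethod
    def load(cls, path) -> "SummarizerModel":
        params, meta = _nn.load_params(path)
        return cls(SummarizerConfig(**meta["config"]), meta["vocab"], params=params)


# ---------------------------------------------------------------------------
# training


def train_summarizer(
    train: Sequence[tuple[DocumentPair, list[LabeledUnit]]],
    dev: Sequence[tuple[DocumentPair, list[LabeledUnit]]],
    config: SummarizerConfig,
    budget_chars: int,
) -> tuple[SummarizerModel, list[dict]]:
    """Minimize unit-level binary cross-entropy; keep the best-dev-ROUGE-1
    checkpoint.  Returns the model and a per-epoch log."""
    if not train:
        raise ValueError("empty training set")
    for pair, labeled in train:
        if not labeled:
            raise ValueError(f"document {pair.doc_id} has no labeled units")
    model = SummarizerModel(config, build_token_vocab([p.source for p, _ in train]))
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    best_score = -1.0
    best_params = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(order), config.batch_docs):
            batch = [train[i] for i in order[b0 : b0 + config.batch_docs]]
            opt.zero_grad()
            losses = []
            for pair, labeled in batch:
                units = [lu.unit for lu in labeled]
                labels = np.array([lu.label for lu in labeled], dtype=np.float64)
                logits = model.unit_logits(model.encode_units(pair.source, units))
                losses.append(_nn.bce_with_logits(logits, labels))
            total = losses[0]
            for loss in losses[1:]:
                total = total + loss
            total = total * Tensor(1.0 / len(losses))
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if dev:
            dev_r1 = _dev_rouge1(model, dev, budget_chars)
            entry["dev_rouge1_f1"] = dev_r1
            if dev_r1 > best_score:
                best_score = dev_r1
                best_params = {k: Tensor(p.data.copy()) for k, p in model.params.items()}
        log.append(entry)
    if best_params is not None:
        model.params = best_params
    return model, log


def _dev_rouge1(model, dev, budget_chars: int) -> float:
    cands, refs = [], []
    for pair, labeled in dev:
        units = [lu.unit for lu in labeled]
        selected, _ = predict_summary(model, pair.source, units, budget_chars)
        cands.append([u.surfaces(pair.source) for u in selected])
        refs.append([[t.surface for t in s.tokens] for s in pair.summary.sentences])
    return evaluate_summaries(cands, refs)["rouge1"] / 100.0


# ---------------------------------------------------------------------------
# inference and evaluation


def predict_summary(
    model: SummarizerModel,
    document: Document,
    units: Sequence[Unit],
    budget_chars: int,
) -> tuple[list[Unit], str]:
    """Budgeted greedy selection by predicted probability; returns the
    selected units in document order and the concatenated summary text."""
    probs = model.score_units(document, units)
    labeled = assign_labels(units, probs.tolist(), budget_chars)
    selected = [lu.unit for lu in labeled if lu.label == 1]
    text = "".join(
        "".join(t.surface for t in u.tokens(document)) for u in selected
    )
    return selected, text


def evaluate_summaries(
    predictions: Sequence[Sequence[Sequence[str]]],
    references: Sequence[Sequence[Sequence[str]]],
) -> dict[str, float]:
    """Corpus-level mean of per-document ROUGE-1/2/L F1, reported x100.

    Each document's prediction and reference is a list of token-sequence
    sentences (for the unit-based candidates, each selected unit is one
    candidate sentence)."""
    if not predictions or len(predictions) != len(references):
        raise ValueError("predictions and references must be aligned and nonempty")
    r1, r2, rl = [], [], []
    for cand_sents, ref_sents in zip(predictions, references):
        cand_flat = [t for s in cand_sents for t in s]
        ref_flat = [t for s in ref_sents for t in s]
        r1.append(rouge_n(cand_flat, ref_flat, 1).f1)
        r2.append(rouge_n(cand_flat, ref_flat, 2).f1)
        nonempty_refs = [s for s in ref_sents if s]
        if nonempty_refs and cand_flat:
            rl.append(rouge_l(nonempty_refs, list(cand_sents)).f1)
        else:
            rl.append(0.0)
    return {
        "rouge1": round(100.0 * float(np.mean(r1)), 2),
        "rouge2": round(100.0 * float(np.mean(r2)), 2),
        "rougeL": round(100.0 * float(np.mean(rl)), 2),
    }
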