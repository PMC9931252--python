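"""Pseudo-label construction for extractive summarization.

Units of one granularity are scored by ROUGE-2 F1 against the full reference
summary, sorted by score (descending, ties broken by document order), and
selected greedily under a character budget.  Selection stops at the first
unit whose inclusion makes the cumulative character length exceed the budget;
that unit is still included ("include-then-stop").  Selected units receive a
positive label.  The default budget is 1,200 characters, the average summary
length in the target archive.

This yields gold-standard extraction labels for training and evaluation
without manual annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_core import Document, DocumentPair, Unit
from .rouge_metrics import rouge_n

DEFAULT_BUDGET_CHARS = 1200


@dataclass(frozen=True)
class LabeledUnit:
    unit: Unit
    rouge2_f1: float
    label: int


@dataclass
class LabeledDocument:
    doc_id: str
    units: list[LabeledUnit]  # document order


@dataclass
class LabeledCorpus:
    documents: list[LabeledDocument]
    granularity: str
    budget_chars: int


def score_units(units: Sequence[Unit], source: Document, reference: Document) -> list[float]:
    """ROUGE-2 F1 of each unit's token sequence against the whole reference
    summary token stream."""
    ref_tokens = reference.surface_stream()
    return [rouge_n(u.surfaces(source), ref_tokens, n=2).f1 for u in units]


def assign_labels(
    units: Sequence[Unit],
    scores: Sequence[float],
    budget_chars: int = DEFAULT_BUDGET_CHARS,
    *,
    include_overflowing: bool = True,
) -> list[LabeledUnit]:
    """Greedy budgeted selection of the highest-scoring units.

    ``include_overflowing`` keeps the unit that first pushes the total past
    the budget (the default reading of "stopped selecting when the result
    exceeded the budget"); when False that unit is dropped and selection
    stops there.
    """
    if budget_chars <= 0:
        raise ValueError("budget_chars must be positive")
    if len(units) != len(scores):
        raise ValueError("units and scores length mismatch")
    order = sorted(range(len(units)), key=lambda i: (-scores[i], i))
    selected: set[int] = set()
    total = 0
    for i in order:
        length = units[i].char_len
        if total + length > budget_chars:
            if include_overflowing:
                selected.add(i)
            break
        selected.add(i)
        total += length
        if total == budget_chars:
            break
    return [
        LabeledUnit(unit=u, rouge2_f1=float(scores[i]), label=int(i in selected))
        for i, u in enumerate(units)
    ]


def label_document(
    pair: DocumentPair,
    units: Sequence[Unit],
    budget_chars: int = DEFAULT_BUDGET_CHARS,
    *,
    include_overflowing: bool = True,
) -> LabeledDocument:
    scores = score_units(units, pair.source, pair.summary)
    return LabeledDocument(
        doc_id=pair.doc_id,
        units=assign_labels(
            units, scores, budget_chars, include_overflowing=include_overflowing
        ),
    )


def label_corpus(
    pairs: Sequence[DocumentPair],
    units_per_doc: Sequence[Sequence[Unit]],
    granularity: str,
    budget_chars: int = DEFAULT_BUDGET_CHARS,
) -> LabeledCorpus:
    docs = [
        label_document(pair, units, budget_chars)
        for pair, units in zip(pairs, units_per_doc)
    ]
    return LabeledCorpus(documents=docs, granularity=granularity, budget_chars=budget_chars)


def split_dataset(
    corpus: Sequence, n_dev: int, n_test: int, seed: int
) -> tuple[list, list, list]:
    """Seed-deterministic disjoint train/dev/test split (remainder = train)."""
    if n_dev + n_test >= len(corpus):
        raise ValueError(
            f"cannot reserve {n_dev}+{n_test} documents from a corpus of {len(corpus)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    dev_idx = set(order[:n_dev].tolist())
    test_idx = set(order[n_dev : n_dev + n_test].tolist())
    train = [corpus[i] for i in range(len(corpus)) if i not in dev_idx and i not in test_idx]
    dev = [corpus[i] for i in sorted(dev_idx)]
    test = [corpus[i] for i in sorted(test_idx)]
    return train, dev, test
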