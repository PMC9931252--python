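"""Shared fixtures: hand-built sentences and small generated corpora."""

from __future__ import annotations

import pytest

from granusum.corpus_core import Document, DocumentPair, SentenceRecord, Token
from granusum.synthetic_data import desk_scale_config, generate_corpus


def make_sentence(spec: str, seg=(), clause=()) -> SentenceRecord:
    """Build a SentenceRecord from 'surface/pos surface/pos ...' shorthand."""
    tokens = []
    for item in spec.split():
        surface, pos = item.rsplit("/", 1)
        tokens.append(Token(surface, pos))
    return SentenceRecord(
        tokens=tokens, gold_segment_boundaries=tuple(seg), gold_clause_boundaries=tuple(clause)
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-document noise-free corpus shared by read-only tests."""
    cfg = desk_scale_config(
        seed=20240915, n_docs=40, noise_fullstop_drop_prob=0.0, noise_linebreak_prob=0.0
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus():
    """A 40-document corpus with default full-stop/line-break noise."""
    return generate_corpus(desk_scale_config(seed=77, n_docs=40))


@pytest.fixture
def tiny_pair():
    """Two-sentence source, one-sentence summary; summary copies tokens c d."""
    src = Document(
        "d1",
        [
            make_sentence("a/noun b/particle c/noun d/verb 。/fullstop", seg=(2,), clause=(2,)),
            make_sentence("e/noun f/verb 。/fullstop"),
        ],
    )
    ref = Document("d1", [make_sentence("c/noun d/verb 。/fullstop")])
    return DocumentPair(source=src, summary=ref)
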