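"""Domain types, corpus I/O, and naive sentence splitting for noisy clinical text.

A corpus is a sequence of :class:`DocumentPair` objects — an inpatient record
(the source) paired with its discharge summary (the reference).  Sentences are
stored pre-tokenized with POS tags and two gold boundary sets: *segment*
boundaries (joins between minimal medically meaningful units) and *clause*
boundaries (a finer, phrase-level segmentation).  Boundaries are integer
positions *between* tokens; position ``b`` separates token ``b-1`` from token
``b``, so valid boundaries satisfy ``0 < b < len(tokens)``.  The sentence-final
position is never stored: a sentence with ``k`` units carries ``k-1``
boundaries.

The on-disk format is UTF-8 JSON-lines, one document pair per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

POS_TAGS = frozenset(
    {
        "noun",
        "noun_nonindependent",
        "verb",
        "particle",
        "adjective",
        "adverb",
        "fullstop",
        "comma",
        "paren_open",
        "paren_close",
        "linebreak",
        "other",
    }
)

GRANULARITIES = ("sentence", "segment", "clause")

#: characters that terminate a sentence under splitting rule (a)
FULL_STOP_CHARS = frozenset({"。", "."})  # 。 and ASCII period
LINE_BREAK_CHAR = "\n"


class CorpusValidationError(ValueError):
    """Raised when a corpus record violates a structural invariant."""


@dataclass(frozen=True)
class Token:
    """A surface form with its part-of-speech tag."""

    surface: str
    pos: str

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise CorpusValidationError(f"unknown POS tag {self.pos!r}")

    @property
    def char_len(self) -> int:
        return len(self.surface)


@dataclass
class SentenceRecord:
    """A tokenized sentence with gold segment and clause boundary sets."""

    tokens: list[Token]
    gold_segment_boundaries: tuple[int, ...] = ()
    gold_clause_boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.gold_segment_boundaries = tuple(sorted(set(self.gold_segment_boundaries)))
        self.gold_clause_boundaries = tuple(sorted(set(self.gold_clause_boundaries)))
        n = len(self.tokens)
        if n == 0:
            raise CorpusValidationError("sentence must contain at least one token")
        for name, bounds in (
            ("segment", self.gold_segment_boundaries),
            ("clause", self.gold_clause_boundaries),
        ):
            for b in bounds:
                if not (0 < b < n):
                    raise CorpusValidationError(
                        f"{name} boundary {b} out of range for {n}-token sentence"
                    )

    @property
    def raw(self) -> str:
        """The sentence text, reconstructed by concatenating token surfaces."""
        return "".join(t.surface for t in self.tokens)

    @property
    def char_len(self) -> int:
        return sum(t.char_len for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Document:
    doc_id: str
    sentences: list[SentenceRecord]

    def __post_init__(self) -> None:
        if not self.sentences:
            raise CorpusValidationError(f"document {self.doc_id!r} has no sentences")

    def token_stream(self) -> list[Token]:
        """All tokens of the document in reading order."""
        return [t for s in self.sentences for t in s.tokens]

    def surface_stream(self) -> list[str]:
        return [t.surface for s in self.sentences for t in s.tokens]


@dataclass
class DocumentPair:
    """A source document (inpatient record) and its reference summary."""

    source: Document
    summary: Document
    #: synthetic corpora only: maps summary unit "sent:start:end" -> source
    #: unit "sent:start:end" for every copied segment
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def doc_id(self) -> str:
        return self.source.doc_id


@dataclass(frozen=True)
class Unit:
    """A half-open token interval ``[start, end)`` inside one sentence."""

    sentence_index: int
    start: int
    end: int
    granularity: str
    char_len: int

    def __post_init__(self) -> None:
        if self.granularity not in GRANULARITIES:
            raise CorpusValidationError(f"unknown granularity {self.granularity!r}")
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(f"bad unit interval [{self.start},{self.end})")

    def tokens(self, doc: Document) -> list[Token]:
        return doc.sentences[self.sentence_index].tokens[self.start : self.end]

    def surfaces(self, doc: Document) -> list[str]:
        return [t.surface for t in self.tokens(doc)]


# ---------------------------------------------------------------------------
# sentence splitting


def split_sentences(raw_text: str) -> list[str]:
    """Split raw noisy text into sentences with two naive rules.

    (a) a sentence ends at every full-stop character;
    (b) a line break not immediately preceded by a full stop also ends a
        sentence.  Line-break characters themselves are dropped, so the
        concatenation of the output plus the removed breaks equals the input.

    Empty input yields an empty list; no empty sentences are emitted.
    The function is idempotent on its own output.
    """
    sentences: list[str] = []
    buf: list[str] = []
    for ch in raw_text:
        if ch in FULL_STOP_CHARS:
            buf.append(ch)
            sentences.append("".join(buf))
            buf = []
        elif ch == LINE_BREAK_CHAR:
            if buf:  # rule (b): break ends the pending statement
                sentences.append("".join(buf))
                buf = []
            # a break right after a full stop (or another break) is noise
        else:
            buf.append(ch)
    if buf:
        sentences.append("".join(buf))
    return sentences


# ---------------------------------------------------------------------------
# unit enumeration


def enumerate_units(
    doc: Document,
    granularity: str,
    boundaries: Sequence[Sequence[int]] | None = None,
) -> list[Unit]:
    """Partition every sentence of ``doc`` into units of one granularity.

    ``boundaries`` gives, per sentence, the internal split positions.  When
    omitted, the gold boundary sets stored on the sentences are used
    (``granularity == "sentence"`` ignores boundaries entirely).  The returned
    units partition each sentence exactly, in document order.
    """
    if granularity not in GRANULARITIES:
        raise CorpusValidationError(f"unknown granularity {granularity!r}")
    units: list[Unit] = []
    for i, sent in enumerate(doc.sentences):
        n = len(sent.tokens)
        if granularity == "sentence":
            bounds: tuple[int, ...] = ()
        elif boundaries is not None:
            bounds = tuple(sorted(set(boundaries[i])))
        elif granularity == "segment":
            bounds = sent.gold_segment_boundaries
        else:
            bounds = sent.gold_clause_boundaries
        for b in bounds:
            if not (0 < b < n):
                raise CorpusValidationError(
                    f"boundary {b} out of range for {n}-token sentence {i}"
                )
        edges = [0, *bounds, n]
        for a, b in zip(edges, edges[1:]):
            units.append(
                Unit(
                    sentence_index=i,
                    start=a,
                    end=b,
                    granularity=granularity,
                    char_len=sum(t.char_len for t in sent.tokens[a:b]),
                )
            )
    return units


# ---------------------------------------------------------------------------
# corpus I/O


def _sentence_to_json(sent: SentenceRecord) -> dict:
    return {
        "tokens": [{"surface": t.surface, "pos": t.pos} for t in sent.tokens],
        "seg_bounds": list(sent.gold_segment_boundaries),
        "clause_bounds": list(sent.gold_clause_boundaries),
    }


def _sentence_from_json(obj: Mapping) -> SentenceRecord:
    return SentenceRecord(
        tokens=[Token(t["surface"], t["pos"]) for t in obj["tokens"]],
        gold_segment_boundaries=tuple(obj.get("seg_bounds", ())),
        gold_clause_boundaries=tuple(obj.get("clause_bounds", ())),
    )


def pair_to_json(pair: DocumentPair) -> dict:
    obj = {
        "doc_id": pair.doc_id,
        "source": [_sentence_to_json(s) for s in pair.source.sentences],
        "summary": [_sentence_to_json(s) for s in pair.summary.sentences],
    }
    if pair.provenance:
        obj["provenance"] = dict(sorted(pair.provenance.items()))
    return obj


def pair_from_json(obj: Mapping) -> DocumentPair:
    doc_id = obj["doc_id"]
    return DocumentPair(
        source=Document(doc_id, [_sentence_from_json(s) for s in obj["source"]]),
        summary=Document(doc_id, [_sentence_from_json(s) for s in obj["summary"]]),
        provenance=dict(obj.get("provenance", {})),
    )


def write_corpus(pairs: Iterable[DocumentPair], path) -> None:
    """Write a corpus as UTF-8 JSON-lines, one document pair per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for pair in pairs:
            fh.write(json.dumps(pair_to_json(pair), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_corpus(path) -> list[DocumentPair]:
    """Read a JSON-lines corpus, validating every record.

    Malformed lines and out-of-range boundaries raise
    :class:`CorpusValidationError` naming the offending line.
    """
    pairs: list[DocumentPair] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"line {lineno}: malformed JSON ({exc})") from exc
            try:
                pair = pair_from_json(obj)
            except (KeyError, TypeError, CorpusValidationError) as exc:
                raise CorpusValidationError(f"line {lineno}: {exc}") from exc
            if pair.doc_id in seen:
                raise CorpusValidationError(f"line {lineno}: duplicate doc_id {pair.doc_id!r}")
            seen.add(pair.doc_id)
            pairs.append(pair)
    return pairs


def validate_corpus(pairs: Sequence[DocumentPair]) -> None:
    """Check cross-record invariants (unique ids, provenance references)."""
    seen: set[str] = set()
    for pair in pairs:
        if pair.doc_id in seen:
            raise CorpusValidationError(f"duplicate doc_id {pair.doc_id!r}")
        seen.add(pair.doc_id)
        for key, val in pair.provenance.items():
            _check_unit_ref(key, pair.summary, "provenance key")
            _check_unit_ref(val, pair.source, "provenance value")


def _check_unit_ref(ref: str, doc: Document, what: str) -> None:
    try:
        sent_i, start, end = (int(x) for x in ref.split(":"))
    except ValueError as exc:
        raise CorpusValidationError(f"{what} {ref!r} is not 'sent:start:end'") from exc
    if not (0 <= sent_i < len(doc.sentences)):
        raise CorpusValidationError(f"{what} {ref!r}: sentence index out of range")
    n = len(doc.sentences[sent_i].tokens)
    if not (0 <= start < end <= n):
        raise CorpusValidationError(f"{what} {ref!r}: span out of range for {n} tokens")


def unit_ref(sentence_index: int, start: int, end: int) -> str:
    """Canonical provenance key for a unit span."""
    return f"{sentence_index}:{start}:{end}"


def parse_unit_ref(ref: str) -> tuple[int, int, int]:
    sent_i, start, end = (int(x) for x in ref.split(":"))
    return sent_i, start, end


def iter_corpus_sentences(pairs: Sequence[DocumentPair], sides=("source", "summary")) -> Iterator[SentenceRecord]:
    for pair in pairs:
        if "source" in sides:
            yield from pair.source.sentences
        if "summary" in sides:
            yield from pair.summary.sentences
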