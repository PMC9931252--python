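"""Span relations between clinical segments and clauses, and copy-paste rate.

Within one sentence, a segment interval and a clause interval can relate in
four counted ways: **equal** (identical intervals), **inclusive** (the
segment strictly contains the clause), **included** (the clause strictly
contains the segment), and **overlap** (they intersect without containment).
Disjoint pairs are not counted — the statistic is taken over intersecting
pairs only.

The copy-paste rate is the fraction of summary sentences (of a minimum token
length) whose full token sequence occurs verbatim and contiguously in the
source document's token stream — a lower-bound measure of how much of a
discharge summary is copied from the inpatient record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus_core import Document, DocumentPair, Unit, enumerate_units

RELATIONS = ("equal", "inclusive", "included", "overlap")


@dataclass(frozen=True)
class RelationCounts:
    equal: int
    inclusive: int
    included: int
    overlap: int

    @property
    def total(self) -> int:
        return self.equal + self.inclusive + self.included + self.overlap

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {r: 0.0 for r in RELATIONS}
        return {r: getattr(self, r) / t for r in RELATIONS}


def classify_relation(segment: Unit, clause: Unit) -> str:
    """Classify the span relation of a (segment, clause) pair in one sentence."""
    if segment.sentence_index != clause.sentence_index:
        raise ValueError(
            f"units from different sentences: {segment.sentence_index} vs {clause.sentence_index}"
        )
    s0, s1 = segment.start, segment.end
    c0, c1 = clause.start, clause.end
    if (s0, s1) == (c0, c1):
        return "equal"
    if s0 <= c0 and c1 <= s1:
        return "inclusive"
    if c0 <= s0 and s1 <= c1:
        return "included"
    if max(s0, c0) < min(s1, c1):
        return "overlap"
    return "disjoint"


def count_relations(segments: Sequence[Unit], clauses: Sequence[Unit]) -> dict[str, int]:
    """Relation counts over all intersecting pairs within matching sentences."""
    counts = {r: 0 for r in RELATIONS}
    by_sentence: dict[int, list[Unit]] = {}
    for c in clauses:
        by_sentence.setdefault(c.sentence_index, []).append(c)
    for seg in segments:
        for cl in by_sentence.get(seg.sentence_index, ()):
            rel = classify_relation(seg, cl)
            if rel != "disjoint":
                counts[rel] += 1
    return counts


def relation_statistics(
    docs: Sequence[Document],
    segment_boundaries: Sequence[Sequence[Sequence[int]]] | None = None,
    clause_boundaries: Sequence[Sequence[Sequence[int]]] | None = None,
) -> RelationCounts:
    """Aggregate relation counts over a sequence of documents.

    ``segment_boundaries`` / ``clause_boundaries`` give per-document,
    per-sentence boundary sets; when omitted the gold sets stored on the
    sentences are used.
    """
    totals = {r: 0 for r in RELATIONS}
    for d, doc in enumerate(docs):
        seg_b = segment_boundaries[d] if segment_boundaries is not None else None
        cl_b = clause_boundaries[d] if clause_boundaries is not None else None
        segments = enumerate_units(doc, "segment", seg_b)
        clauses = enumerate_units(doc, "clause", cl_b)
        for rel, n in count_relations(segments, clauses).items():
            totals[rel] += n
    return RelationCounts(**totals)


def _contains_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return False
    first = needle[0]
    for i in range(n - m + 1):
        if haystack[i] == first and list(haystack[i : i + m]) == list(needle):
            return True
    return False


def copy_paste_rate(pair: DocumentPair, min_tokens: int = 3) -> float:
    """Fraction of summary sentences copied verbatim from the source.

    Only summary sentences with at least ``min_tokens`` tokens are counted;
    a sentence counts as copied when its full token sequence occurs as a
    contiguous run in the source token stream.
    """
    if min_tokens < 1:
        raise ValueError("min_tokens must be >= 1")
    source_stream = pair.source.surface_stream()
    eligible = 0
    copied = 0
    for sent in pair.summary.sentences:
        surfaces = [t.surface for t in sent.tokens]
        if len(surfaces) < min_tokens:
            continue
        eligible += 1
        if _contains_subsequence(source_stream, surfaces):
            copied += 1
    if eligible == 0:
        return 0.0
    return copied / eligible


def corpus_copy_paste_rate(pairs: Sequence[DocumentPair], min_tokens: int = 3) -> float:
    """Micro-averaged copy-paste rate over a corpus."""
    eligible = 0
    copied = 0
    for pair in pairs:
        source_stream = pair.source.surface_stream()
        for sent in pair.summary.sentences:
            surfaces = [t.surface for t in sent.tokens]
            if len(surfaces) < min_tokens:
                continue
            eligible += 1
            if _contains_subsequence(source_stream, surfaces):
                copied += 1
    return copied / eligible if eligible else 0.0
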