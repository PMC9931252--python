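"""ROUGE-N and union-LCS ROUGE-L.

ROUGE-N is clipped n-gram recall between a candidate and a reference token
sequence: for every n-gram of the reference, the match count is the minimum of
its multiplicities in candidate and reference, summed and divided by the total
number of reference n-grams.  Precision is the same numerator over candidate
n-grams; F1 is their harmonic mean.

ROUGE-L uses the *union* LCS: for each reference sentence r_i, one longest
common subsequence with each candidate sentence is expressed as a set of
reference token positions, and the sizes of the unions of these sets are
summed over reference sentences.  Recall divides by total reference tokens,
precision by total candidate tokens.  For example, with
r = (w1, w2, w3, w4), c1 = (w1, w2, w6, w7) and c2 = (w1, w8, w4, w9), the two
LCSs cover reference positions {0, 1} and {0, 3}; their union {w1, w2, w4} has
size 3, so recall is 3/4.

Degenerate inputs (empty sequences, reference shorter than n) yield zero
scores, never errors: noisy clinical text guarantees such cases.  Token
identity is exact surface match — no stemming or stopword removal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

TokenSeq = Sequence[str]


@dataclass(frozen=True)
class RougeScore:
    recall: float
    precision: float
    f1: float

    @staticmethod
    def from_pr(recall: float, precision: float) -> "RougeScore":
        denom = recall + precision
        f1 = 2.0 * recall * precision / denom if denom > 0 else 0.0
        return RougeScore(recall=recall, precision=precision, f1=f1)


ZERO_SCORE = RougeScore(0.0, 0.0, 0.0)


def _ngrams(tokens: TokenSeq, n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def rouge_n(candidate: TokenSeq, reference: TokenSeq, n: int) -> RougeScore:
    """Clipped n-gram co-occurrence recall/precision/F1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ref_grams = _ngrams(reference, n)
    cand_grams = _ngrams(candidate, n)
    total_ref = sum(ref_grams.values())
    total_cand = sum(cand_grams.values())
    if total_ref == 0 and total_cand == 0:
        return ZERO_SCORE
    match = sum(min(cnt, cand_grams[g]) for g, cnt in ref_grams.items())
    recall = match / total_ref if total_ref else 0.0
    precision = match / total_cand if total_cand else 0.0
    return RougeScore.from_pr(recall, precision)


def _lcs_positions(reference: TokenSeq, candidate: TokenSeq) -> frozenset[int]:
    """Reference positions of one LCS, chosen leftmost-greedily.

    Walks the DP table from the front, matching a reference token whenever the
    match is consistent with an optimal LCS; this yields the lexicographically
    smallest tuple of reference positions among all LCSs, making the union
    deterministic.
    """
    n, m = len(reference), len(candidate)
    if n == 0 or m == 0:
        return frozenset()
    # L[i][j] = LCS length of reference[i:], candidate[j:]
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = L[i], L[i + 1]
        for j in range(m - 1, -1, -1):
            if reference[i] == candidate[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = nxt[j] if nxt[j] >= row[j + 1] else row[j + 1]
    positions: list[int] = []
    i = j = 0
    while i < n and j < m and L[i][j] > 0:
        if reference[i] == candidate[j] and L[i][j] == L[i + 1][j + 1] + 1:
            positions.append(i)
            i += 1
            j += 1
        elif L[i][j + 1] >= L[i + 1][j]:
            # on ties keep the current reference position available so the
            # chosen positions are the leftmost possible
            j += 1
        else:
            i += 1
    return frozenset(positions)


def lcs_union(reference_sentence: TokenSeq, candidate_sentences: Sequence[TokenSeq]) -> int:
    """Size of the union of per-candidate LCS reference-position sets."""
    if not reference_sentence:
        raise ValueError("reference sentence must be nonempty")
    covered: set[int] = set()
    for cand in candidate_sentences:
        covered |= _lcs_positions(reference_sentence, cand)
    return len(covered)


def rouge_l(
    reference_sentences: Sequence[TokenSeq],
    candidate_sentences: Sequence[TokenSeq],
) -> RougeScore:
    """Union-LCS ROUGE-L over sentence-structured summaries."""
    if not reference_sentences:
        raise ValueError("need at least one reference sentence")
    total_ref = sum(len(r) for r in reference_sentences)
    total_cand = sum(len(c) for c in candidate_sentences)
    if total_ref == 0 or total_cand == 0:
        return ZERO_SCORE
    hits = sum(
        lcs_union(r, candidate_sentences) for r in reference_sentences if len(r) > 0
    )
    recall = hits / total_ref
    precision = hits / total_cand
    return RougeScore.from_pr(recall, precision)
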