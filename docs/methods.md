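# Methods

## Problem

Discharge summaries condense a hospital stay into a short document, and a
sizable share of their text is copied from the daily inpatient notes.  An
extractive summarizer must decide *what* to copy, and the unit of extraction
matters: whole sentences drag along irrelevant clauses, while very short
clauses destroy medically meaningful statements.  This package implements a
granularity analysis comparing three unit types — whole **sentences**,
**clinical segments** (the smallest medically meaningful spans, typically one
event such as a diagnosis, an examination, or a treatment), and **clauses**
(shorter, phrase-level spans) — on a synthetic stand-in for a restricted
multi-institutional archive of Japanese health records.

## Pipeline

1. **Sentence splitting** (`corpus_core.split_sentences`).  Clinical notes
   are noisy: full stops go missing and line breaks appear mid-sentence.
   Two naive rules are applied greedily left to right: a sentence ends at
   every full-stop character, and at any line break not immediately preceded
   by a full stop.  Line-break characters are dropped.  Spaces are *not*
   treated as boundaries.
2. **Segment splitting** (`unit_splitters`).  Two rule baselines (split at
   full stops; additionally split before the next independent noun after a
   verb), a POS-cue clause splitter (boundary after every particle and
   verb), and a trainable pointer network.  The pointer network encodes a
   sentence with a single-layer bidirectional Elman recurrence over token
   vectors (word embedding + mean of hashed character 3–5-gram embeddings +
   a part-of-speech embedding; the corpus arrives morphologically tagged) and
   decodes monotonically: starting at token 0, a recurrent decoder points to
   the end position of the current unit among the remaining positions, until
   it points at the sentence end.  Ties in pointer scores break toward the
   earliest position.  Boundary quality is exact-position precision/recall/
   F1, micro-averaged.
3. **Oracle labeling** (`oracle_labeling`).  Each unit is scored by ROUGE-2
   F1 against the full reference-summary token stream, units are sorted by
   score (ties: document order) and selected greedily under a character
   budget.  The unit that first pushes the total past the budget is included
   and selection stops ("include-then-stop"); a flag switches to
   exclude-then-stop.  The default budget is 1,200 characters, the average
   reference-summary length at archive scale.
4. **Unit classification** (`extractive_summarizer`).  Sentences are wrapped
   in begin/separator markers and encoded by a 2-layer self-attention stack
   (hidden 64 by default; the encoder is pluggable so a pretrained clinical
   masked-LM can be substituted).  Segment/clause units are mean-pooled over
   member tokens (markers excluded); sentence units use the begin-marker
   vector directly.  A 1-layer, 2-head unit-level transformer with sinusoidal
   positions contextualizes the unit sequence, and a sigmoid-affine head
   yields extraction probabilities, trained with mean binary cross-entropy
   against the oracle labels.  The checkpoint with the best dev ROUGE-1 is
   kept.  Inference ranks units by probability and applies the same
   include-then-stop budget; whether to threshold instead is an open choice,
   and budgeted ranking was chosen for symmetry with labeling.
5. **Evaluation** (`rouge_metrics`).  ROUGE-N uses clipped multiset n-gram
   matching; ROUGE-L uses the union-LCS formulation: for each reference
   sentence, one LCS per candidate sentence is expressed as a set of
   reference positions and the union is counted; recall divides by reference
   tokens, precision by candidate tokens.  Reported scores are per-document
   means, ×100.  ROUGE is computed over tokens (a flag is the natural place
   to switch to characters).
6. **Span relations** (`relation_analysis`).  Every intersecting
   (segment, clause) pair inside a sentence is classified Equal / Inclusive
   (segment ⊋ clause) / Included (clause ⊋ segment) / Overlap; disjoint pairs
   are not counted.  The copy-paste rate is the fraction of summary
   sentences (≥ 3 tokens by default) whose token sequence occurs verbatim
   and contiguously in the source document.

## Synthetic corpus

Real corpora of this kind are access-restricted, so `synthetic_data`
generates parallel corpora with the statistical structure the analysis
depends on.

* **Sources.**  Each sentence concatenates 1..m "events" (m is shifted
  Poisson with mean 2.18).  An event is ~3.7 tokens ending in a cue — a
  verb (probability 0.6) or a comma — and usually opens with a noun, so
  that segment boundaries are learnable and the verb→noun heuristic is
  partially right.  Sentences end with a full stop; tokens average ~2
  characters, giving ~9 tokens and ~19 characters per sentence.  Clause
  boundaries refine segment boundaries by also splitting after particles
  with probability 0.3 (so gold clauses are nested in gold segments —
  predicted clause units are not).
* **Vocabulary.**  2,000 types with POS-partitioned roles.  Particles and
  non-independent nouns are tiny closed classes; verbs share one of three
  2-character suffixes so character-n-gram composition generalizes to
  unseen verbs.  A small (~3%) pool of high-frequency "medical" nouns opens
  the salient events; this skew is what lets a from-scratch encoder learn
  which content is copy-worthy.
* **Salience.**  Each source event is medical/salient with probability 0.3.
  Only salient segments are copy-eligible; this encodes the premise that
  medical events are the central, copied statements and the rest is noise.
* **Summaries.**  Built sentence by sentence until the character budget is
  reached: with probability 0.25 a verbatim whole-sentence copy (the
  measurable copy-and-paste regime, inside the reported 20–31% band); with
  probability 0.5 a recombination of 1–3 salient segments sampled without
  replacement across source sentences (the dominant mechanism — concepts
  extracted and recombined in new contexts — which is what makes segment
  granularity the planted optimum); otherwise a freshly generated
  non-salient filler sentence (summary content the copy model cannot
  account for; its composition is a free choice).  Every copied span is
  recorded in a provenance map.
* **Noise.**  Each sentence loses its trailing full stop with probability
  0.10 and gains a mid-sentence line break with probability 0.05.
* What the generator does **not** emulate: real lexical semantics, Zipfian
  frequencies beyond the medical-noun pool, structured medication lines,
  abstractive paraphrase, or inter-annotator disagreement.  Passing tests
  therefore demonstrate that the pipeline recovers planted structure of the
  stated kind, not clinical-grade performance on real records.

## Problem sizes

Archive-scale defaults (24,641 documents, 192 source sentences each,
1,200-character summaries) describe the target data.  Experiments and tests
run at desk scale: 400 documents, 12 source sentences per document, an
80-character summary budget (preserving the archive's roughly 3:1 ratio of
source characters to budget), 1,000 training sentences for the splitter
(12 epochs, hidden 32), and 10 epochs (hidden 32, learning rate 5e-3,
batches of 8 documents) per summarizer.  A full experiment takes a few
minutes on one CPU.

## Numerical choices

* All neural code runs on a small in-package reverse-mode autodiff core
  (`_nn`), float64 throughout; training is seeded and single-threaded, so
  identical configurations reproduce byte-identical reports.
* 0/0 ROUGE cases return 0 rather than raising — degenerate inputs are
  routine in noisy clinical text.
* The union-LCS backtrace picks, per candidate, the leftmost set of
  reference positions consistent with an optimal LCS (ties in the DP walk
  advance the candidate index).  A different choice of per-candidate LCS
  could occasionally give a *larger* union; the deterministic leftmost rule
  is preferred over union maximization for reproducibility, and the gap did
  not occur on exhaustive enumeration up to length 6.
* Greedy selection ties break by document order everywhere; pointer-score
  ties break toward the earliest position.
* Boundary positions are integers strictly inside the sentence; the final
  position is never stored (a sentence with k units has k−1 boundaries).
* Dataset splits are seed-deterministic permutations; every stage seed is
  derived from the master seed and stays below 2^31.

## Design choices that were genuinely open

* **Budget semantics**: "stop when the result exceeds the budget" is read as
  include-then-stop; the overflowing unit is kept.  The alternative is a
  config flag.
* **ROUGE-2 reference side** for labeling is the whole summary token stream,
  not per-sentence maxima — the simplest consistent reading.
* **Labeling on predicted segments** (the trained pointer splitter) by
  default, mirroring the full-archive procedure; gold boundaries are an
  ablation flag.
* **Relation statistics** are computed over source *and* summary documents,
  on the predicted segmentations (pointer segments vs POS-cue clauses);
  gold-boundary statistics are reported alongside and contain only
  Equal/Inclusive by construction.
* **Micro-averaging** for boundary metrics; **per-document means** for
  ROUGE tables.
* **Per-granularity summarizer training** (three models) rather than one
  shared encoder.
* The copy-paste criterion (minimum 3 tokens, exact contiguous match) is
  parameterized since the original preliminary measurement is undisclosed.

## Known limitations

* The summarizer learns which units are *likely* copied (salience), not
  which were actually copied — the planted copy choice among salient events
  is irreducibly random — so trained ROUGE sits well below the oracle-label
  ceiling at every granularity; the granularity comparison is the object of
  interest, not absolute scores.
* The pointer decoder is greedy; no beam search.
* Unknown-word handling relies on hashed character n-grams; with no
  pretrained vectors, truly unseen morphology degrades gracefully rather
  than transferring.
* ROUGE is both the labeling signal and the evaluation metric, a standard
  but circular practice inherited from the experimental design.
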