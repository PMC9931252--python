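# granusum

**What is the right granularity for extractive summarization of clinical
records?**  Discharge summaries are partly assembled by copying from daily
inpatient notes — roughly a fifth to a third of their sentences verbatim —
but much of the copied content is *recombined*: clinically meaningful
fragments are extracted and rearranged into new sentences.  `granusum`
implements the full analysis pipeline for comparing three extraction units —
whole **sentences**, **clinical segments** (the smallest medically
meaningful spans), and **clauses** (shorter, phrase-level spans) — and ships
a synthetic parallel-corpus generator standing in for the restricted
hospital archive such studies run on, so that every stage is reproducible on
a laptop.

It is aimed at clinical-NLP researchers studying summarization of electronic
health records, and at anyone who needs a clean, dependency-light
implementation of the building blocks below.

## The method

Given parallel (inpatient record *D*, discharge summary *R*) pairs:

1. **Sentence splitting.**  Noisy notes are split by two naive rules: a
   sentence ends at a full stop, or at a line break not preceded by one.
2. **Segment splitting.**  A pointer network (encode–decode–point) places
   segment boundaries: a BiRNN encodes token vectors (word + hashed
   character n-gram + POS embeddings); a recurrent decoder starting at token
   0 repeatedly points to the end of the current unit, giving a strictly
   increasing boundary sequence.  Rule baselines (full-stop; full-stop &
   verb) and a POS-cue clause splitter are included, evaluated by
   exact-position boundary precision/recall/F1.
3. **Oracle labels.**  Each unit *s*ᵢⱼ is scored by ROUGE-2 F1 against *R*;
   units are sorted by score and selected greedily until the selection
   exceeds a character budget (1,200 characters at archive scale); selected
   units get label *y*ᵢⱼ = 1.
4. **Unit classifier.**  Token encoder → mean pooling per unit
   (s′ᵢⱼ = 1/k Σₖ wᵢⱼₖ; the sentence unit uses its begin-marker vector) →
   unit-level transformer (S″ = Transformer(S′)) → p(s″ᵢⱼ) = σ(W₀s″ᵢⱼ + b₀),
   trained with binary cross-entropy against *y*ᵢⱼ.  Inference ranks units
   by p and applies the same character budget.
5. **Evaluation.**  ROUGE-1/2 (clipped n-gram counts) and union-LCS ROUGE-L:
   LCS∪(rᵢ, C) counts reference positions covered by the union of the
   per-candidate longest common subsequences; recall divides by reference
   tokens, precision by candidate tokens.
6. **Span relations.**  Each intersecting (segment, clause) pair is
   classified Equal / Inclusive / Included / Overlap; the copy-paste rate
   measures summary sentences occurring verbatim in the source.

## Worked example

Generate a small corpus, train the splitter and the three summarizers, and
print every report:

```bash
granusum run --config experiment.yaml --out results/
```

with `experiment.yaml` simply setting a seed (all other parameters have
documented defaults — 400 synthetic documents, 12 source sentences each, an
80-character summary budget):

```yaml
seed: 1
```

The run writes `table5.json` … `table8.json`, `report.json` and `report.md`.
With seed 1 the printed reports contain:

* **Segmentation** (boundary F1 vs gold segments, test sentences):
  pointer network **0.971**, full-stop & verb 0.615, POS-cue clause splitter
  0.387, full-stop 0.000.  The learned splitter dominates the rules, and the
  clause grammar's low F1 confirms that clauses and clinical segments are
  genuinely different units.
* **Summarization** (test-set mean ROUGE F1 × 100):

  | unit | ROUGE-1 | ROUGE-2 | ROUGE-L |
  |---|---|---|---|
  | sentence | 34.64 | 17.61 | 38.11 |
  | **segment** | **47.51** | **31.74** | **51.08** |
  | clause | 37.63 | 18.81 | 41.57 |

  Clinical segments beat both whole sentences (which waste budget on
  non-salient sibling clauses) and clauses (which fragment concepts and
  misalign with the copied spans).
* **Unit sizes**: 1 / 2.18 / 3.34 units per sentence and 24.2 / 11.1 / 7.3
  characters per unit for sentence / segment / clause — segments sit
  between sentences and clauses.
* **Relations** (predicted segment vs clause spans, all documents):
  Inclusive 61.9%, Equal 14.7%, Overlap 11.9%, Included 11.5%.
* **Copy-paste rate**: 27.9% of summary sentences occur verbatim in their
  source document, inside the 20–31% regime the generator plants.

The same numbers are obtainable in Python:

```python
from granusum.experiment import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(seed=1), out_dir="results/")
print(report["table6"]["segment"]["rouge1"])   # 47.51
```

Individual stages are importable on their own — `granusum.rouge_metrics`
for ROUGE-N / union-LCS ROUGE-L, `granusum.unit_splitters` for the pointer
splitter, `granusum.oracle_labeling` for budgeted pseudo-labels,
`granusum.synthetic_data` for corpus generation — and each has a CLI
subcommand (`granusum gen | corpus | rouge | split | label | summarize |
relations | copyrate | run`).

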