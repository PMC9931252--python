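"""End-to-end granularity experiment.

Pipeline: obtain a parallel corpus (generated or loaded), split it into
train/dev/test, train the pointer-network segment splitter on gold segment
boundaries, produce the three unit granularities (whole sentences; predicted
segments; clause-rule units), build oracle extraction labels under the
character budget, train one summarizer per granularity, and evaluate on the
test documents.  The report bundle contains:

* ``table5`` — boundary precision/recall/F1 of every splitter against gold
  segment boundaries on the test sentences;
* ``table6`` — per-granularity ROUGE-1/2/L of the trained summarizers (plus
  the oracle-label ceiling for each granularity);
* ``table7`` — units/sentence, tokens/unit, chars/unit for the units each
  granularity actually used;
* ``table8`` — Equal/Inclusive/Included/Overlap counts between segment and
  clause units over all source and summary sentences, for both the predicted
  and the gold segmentations;
* the corpus copy-paste rate.

Every stage derives its seed from the master seed, so a rerun with the same
configuration is numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .corpus_core import Document, DocumentPair, enumerate_units, read_corpus
from .extractive_summarizer import (
    SummarizerConfig,
    evaluate_summaries,
    predict_summary,
    train_summarizer,
)
from .oracle_labeling import label_document, split_dataset
from .relation_analysis import corpus_copy_paste_rate, relation_statistics
from .synthetic_data import GeneratorConfig, desk_scale_config, generate_corpus
from .unit_splitters import (
    PointerConfig,
    evaluate_boundaries,
    split_clauses_pos,
    split_fullstop,
    split_fullstop_verb,
    train_pointer_splitter,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int
    generator: GeneratorConfig | None = None
    corpus_path: str | None = None
    granularities: tuple[str, ...] = ("sentence", "segment", "clause")
    budget_chars: int | None = None  # None: the generator's summary budget, else 1200
    n_dev: int = 20
    n_test: int = 20
    splitter_epochs: int = 12
    splitter_hidden: int = 32
    splitter_max_sentences: int = 1000
    summarizer_epochs: int = 10
    summarizer_hidden: int = 32
    use_gold_segments: bool = False  # label/summarize on gold instead of predicted segments
    use_gold_clauses: bool = False

    def resolved_generator(self) -> GeneratorConfig | None:
        if self.corpus_path is not None:
            return None
        if self.generator is not None:
            return self.generator
        return desk_scale_config(seed=_stage_seed(self.seed, 0))


def _stage_seed(master: int, stage: int) -> int:
    return (master * 1000003 + stage * 7919) % (2**31 - 1)


def _sentence_boundaries(model, doc: Document) -> list[set[int]]:
    return [model.predict(s) for s in doc.sentences]


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run every stage; return (and optionally write) the report bundle."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "config": _config_dict(config)}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    # stage 1: corpus ------------------------------------------------------
    try:
        if config.corpus_path is not None:
            corpus = read_corpus(config.corpus_path)
            budget = config.budget_chars or 1200
        else:
            gen_cfg = config.resolved_generator()
            corpus = generate_corpus(gen_cfg)
            budget = config.budget_chars or gen_cfg.summary_char_budget
        logger.info("corpus: %d document pairs, budget %d chars", len(corpus), budget)
    except Exception as exc:
        raise ExperimentError(f"corpus stage failed: {exc}") from exc
    _partial(out_path, report)

    # stage 2: split -------------------------------------------------------
    try:
        train_pairs, dev_pairs, test_pairs = split_dataset(
            corpus, config.n_dev, config.n_test, seed=_stage_seed(config.seed, 1)
        )
    except Exception as exc:
        raise ExperimentError(f"dataset-split stage failed: {exc}") from exc
    report["split"] = {
        "train": len(train_pairs),
        "dev": len(dev_pairs),
        "test": len(test_pairs),
    }

    # stage 3: segment splitter -------------------------------------------
    try:
        rng = np.random.default_rng(_stage_seed(config.seed, 2))
        train_sents = [s for p in train_pairs for s in p.source.sentences]
        if len(train_sents) > config.splitter_max_sentences:
            keep = rng.choice(len(train_sents), config.splitter_max_sentences, replace=False)
            train_sents = [train_sents[i] for i in sorted(keep)]
        dev_sents = [s for p in dev_pairs for s in p.source.sentences]
        test_sents = [s for p in test_pairs for s in p.source.sentences]
        pointer_cfg = PointerConfig(
            seed=_stage_seed(config.seed, 3),
            hidden_size=config.splitter_hidden,
            epochs=config.splitter_epochs,
        )
        splitter, splitter_log = train_pointer_splitter(train_sents, dev_sents, pointer_cfg)
        gold_test = [set(s.gold_segment_boundaries) for s in test_sents]
        table5 = {}
        for name, preds in (
            ("fullstop", [split_fullstop(s) for s in test_sents]),
            ("fullstop_verb", [split_fullstop_verb(s) for s in test_sents]),
            ("clause_pos", [split_clauses_pos(s) for s in test_sents]),
            ("pointer", [splitter.predict(s) for s in test_sents]),
        ):
            ev = evaluate_boundaries(preds, gold_test)
            table5[name] = {
                "precision": round(ev.precision, 4),
                "recall": round(ev.recall, 4),
                "f1": round(ev.f1, 4),
            }
        report["table5"] = table5
        report["splitter_log"] = splitter_log
        logger.info("splitter test F1: %s", {k: v["f1"] for k, v in table5.items()})
    except ExperimentError:
        raise
    except Exception as exc:
        raise ExperimentError(f"splitter stage failed: {exc}") from exc
    _partial(out_path, report)

    # stage 4: per-granularity labeling, training, evaluation --------------
    try:
        # boundary sets for every document, per granularity
        def units_for(pair: DocumentPair, granularity: str):
            doc = pair.source
            if granularity == "sentence":
                return enumerate_units(doc, "sentence")
            if granularity == "segment":
                if config.use_gold_segments:
                    return enumerate_units(doc, "segment")
                return enumerate_units(doc, "segment", _sentence_boundaries(splitter, doc))
            if config.use_gold_clauses:
                return enumerate_units(doc, "clause")
            return enumerate_units(
                doc, "clause", [split_clauses_pos(s) for s in doc.sentences]
            )

        table6: dict = {}
        table7: dict = {}
        for gi, gran in enumerate(config.granularities):
            labeled = {
                side: [
                    (pair, label_document(pair, units_for(pair, gran), budget).units)
                    for pair in pairs
                ]
                for side, pairs in (
                    ("train", train_pairs),
                    ("dev", dev_pairs),
                    ("test", test_pairs),
                )
            }
            sum_cfg = SummarizerConfig(
                seed=_stage_seed(config.seed, 10 + gi),
                hidden=config.summarizer_hidden,
                epochs=config.summarizer_epochs,
            )
            model, train_log = train_summarizer(
                labeled["train"], labeled["dev"], sum_cfg, budget
            )
            cands, refs, oracle_cands = [], [], []
            for pair, lab_units in labeled["test"]:
                units = [lu.unit for lu in lab_units]
                selected, _ = predict_summary(model, pair.source, units, budget)
                cands.append([u.surfaces(pair.source) for u in selected])
                oracle_cands.append(
                    [lu.unit.surfaces(pair.source) for lu in lab_units if lu.label == 1]
                )
                refs.append([[t.surface for t in s.tokens] for s in pair.summary.sentences])
            table6[gran] = evaluate_summaries(cands, refs)
            table6[gran]["oracle_rouge1"] = evaluate_summaries(oracle_cands, refs)["rouge1"]
            table6[gran]["train_log"] = train_log

            # table 7: statistics of the units actually used (all splits)
            n_sent = n_units = n_tok = n_chr = 0
            for side in ("train", "dev", "test"):
                for pair, lab_units in labeled[side]:
                    n_sent += len(pair.source.sentences)
                    for lu in lab_units:
                        n_units += 1
                        n_tok += lu.unit.end - lu.unit.start
                        n_chr += lu.unit.char_len
            table7[gran] = {
                "units_per_sentence": round(n_units / n_sent, 2),
                "tokens_per_unit": round(n_tok / n_units, 2),
                "chars_per_unit": round(n_chr / n_units, 2),
            }
            logger.info("granularity %s: ROUGE-1 %.2f", gran, table6[gran]["rouge1"])
        report["table6"] = table6
        report["table7"] = table7
    except ExperimentError:
        raise
    except Exception as exc:
        raise ExperimentError(f"summarization stage failed: {exc}") from exc
    _partial(out_path, report)

    # stage 5: relation statistics and copy rate ---------------------------
    try:
        all_docs: list[Document] = []
        for pair in corpus:
            all_docs.append(pair.source)
            all_docs.append(pair.summary)
        gold_counts = relation_statistics(all_docs)
        pred_seg = [
            _sentence_boundaries(splitter, doc) for doc in all_docs
        ]
        pred_cl = [[split_clauses_pos(s) for s in doc.sentences] for doc in all_docs]
        pred_counts = relation_statistics(all_docs, pred_seg, pred_cl)
        report["table8"] = {
            "predicted": {
                "counts": dataclasses.asdict(pred_counts),
                "proportions": {
                    k: round(v, 4) for k, v in pred_counts.proportions.items()
                },
            },
            "gold": {
                "counts": dataclasses.asdict(gold_counts),
                "proportions": {
                    k: round(v, 4) for k, v in gold_counts.proportions.items()
                },
            },
        }
        report["copy_paste_rate"] = round(corpus_copy_paste_rate(corpus), 4)
    except Exception as exc:
        raise ExperimentError(f"relation stage failed: {exc}") from exc

    if out_path is not None:
        _write_reports(out_path, report)
    return report


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["granularities"] = list(d["granularities"])
    return d


def _partial(out_path: Path | None, report: dict) -> None:
    """Persist partial results so a failed stage leaves its predecessors."""
    if out_path is not None:
        (out_path / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False)
        )


def _write_reports(out_path: Path, report: dict) -> None:
    for table in ("table5", "table6", "table7", "table8"):
        (out_path / f"{table}.json").write_text(
            json.dumps(report[table], indent=2, sort_keys=True, ensure_ascii=False)
        )
    (out_path / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False)
    )
    (out_path / "report.md").write_text(_render_markdown(report))


def _render_markdown(report: dict) -> str:
    lines = ["# Granularity experiment report", ""]
    lines.append("## Segmentation (boundary P/R/F1 vs gold segments)")
    for name, row in report["table5"].items():
        lines.append(
            f"- {name}: P={row['precision']:.3f} R={row['recall']:.3f} F1={row['f1']:.3f}"
        )
    lines.append("")
    lines.append("## Summarization ROUGE (x100, test set)")
    lines.append("| unit | ROUGE-1 | ROUGE-2 | ROUGE-L |")
    lines.append("|---|---|---|---|")
    for gran, row in report["table6"].items():
        lines.append(
            f"| {gran} | {row['rouge1']:.2f} | {row['rouge2']:.2f} | {row['rougeL']:.2f} |"
        )
    lines.append("")
    lines.append("## Unit granularity")
    lines.append("| unit | units/sentence | tokens/unit | chars/unit |")
    lines.append("|---|---|---|---|")
    for gran, row in report["table7"].items():
        lines.append(
            f"| {gran} | {row['units_per_sentence']} | {row['tokens_per_unit']} |"
            f" {row['chars_per_unit']} |"
        )
    lines.append("")
    props = report["table8"]["predicted"]["proportions"]
    lines.append("## Segment/clause span relations (predicted segmentations)")
    lines.append(
        "Equal {equal:.1%}, Inclusive {inclusive:.1%}, Included {included:.1%},"
        " Overlap {overlap:.1%}".format(**props)
    )
    lines.append("")
    lines.append(f"Copy-paste rate: {report['copy_paste_rate']:.1%}")
    lines.append("")
    return "\n".join(lines)
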