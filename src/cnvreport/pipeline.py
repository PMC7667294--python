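"""End-to-end workflows over the corpus and interpretation stages.

These functions wire the per-module operations into the experiments the
package is validated with: segmentation + matching recovery against planted
truth, the weak-label → active-learning → classifier loop, and the
interpretation benchmark on co-designed knowledge bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytoband import CytobandTable
from .embeddings import EmbeddingTable, hashed_embeddings, vocabulary
from .evaluation import macro_f1
from .interpretation import interpret_cnv
from .labeling import (
    DEFAULT_RULES,
    KeywordRuleTable,
    generate_programming_labels,
    select_for_active_labeling,
)
from .matching import match_cnvs
from .models import CATEGORIES, Category, ClinicalReport, Sentence, SubParagraph
from .segmentation import segment_paragraph, train_begin_classifier
from .sequence_models import TrainingConfig, classify_corpus, train_corpus_classifier
from .simulate import CorpusTruth, InterpFixtures
from .text import split_sentences


def segmentation_matching_recovery(
    reports: list[ClinicalReport],
    truth: CorpusTruth,
    cytobands: CytobandTable,
) -> tuple[float, pd.DataFrame]:
    """Fraction of planted CNV ↔ sub-paragraph pairs recovered end to end.

    A pair counts as recovered when the begin-classifier segmentation
    produces a sub-paragraph with exactly the planted sentence span and the
    relation-score matcher assigns the CNV to it.
    """
    model = train_begin_classifier(reports)
    rows = []
    for report in reports:
        rt = truth.by_report[report.report_id]
        sentences = split_sentences(report.paragraph)
        subs = segment_paragraph(sentences, model, report_id=report.report_id)
        assignment = match_cnvs(report.cnvs, subs, cytobands)
        spans = [(sub.sentences[0].index, sub.sentences[-1].index + 1) for sub in subs]
        true_spans = rt.sub_spans
        for cnv_idx, true_sub in rt.cnv_to_sub.items():
            got = assignment[cnv_idx]
            rows.append(
                {
                    "report_id": report.report_id,
                    "cnv_index": cnv_idx,
                    "recovered": spans[got] == true_spans[true_sub],
                }
            )
    df = pd.DataFrame(rows)
    return float(df["recovered"].mean()), df


def gold_subparagraphs(
    reports: list[ClinicalReport], truth: CorpusTruth
) -> tuple[list[SubParagraph], list[list[Category]]]:
    """Sub-paragraphs cut at the planted boundaries, with gold categories.

    This mirrors the manually corrected corpus the classifier stage trains
    on; segmentation quality is measured separately.
    """
    subs: list[SubParagraph] = []
    gold: list[list[Category]] = []
    for report in reports:
        rt = truth.by_report[report.report_id]
        sentences = split_sentences(report.paragraph)
        if len(sentences) != len(rt.categories):
            raise ValueError(f"report {report.report_id}: sentence/category mismatch")
        for sub_idx, (lo, hi) in enumerate(rt.sub_spans):
            sub = SubParagraph(
                sentences=sentences[lo:hi],
                source_report_id=report.report_id,
                matched_cnv_index=sub_idx,
            )
            subs.append(sub)
            gold.append(rt.categories[lo:hi])
    return subs, gold


def _flatten_predictions(subs: list[SubParagraph]) -> list[str]:
    return [Category(s.category).value for sub in subs for s in sub.sentences]


def _flatten_gold(gold: list[list[Category]]) -> list[str]:
    return [c.value for cats in gold for c in cats]


@dataclass
class ActiveLearningResult:
    programming_macro_f1: float
    macro_f1_by_model: dict[str, float]
    n_selected: int
    n_train: int
    n_heldout: int


def active_learning_experiment(
    reports: list[ClinicalReport],
    truth: CorpusTruth,
    config: TrainingConfig | None = None,
    model_types: tuple[str, ...] = ("nb", "nb_crf"),
    rules: KeywordRuleTable = DEFAULT_RULES,
    holdout_fraction: float = 0.2,
    table: EmbeddingTable | None = None,
) -> ActiveLearningResult:
    """The bootstrap loop: weak labels → model → query → expert labels → model.

    1. keyword rules give every sentence a programming (weak) label;
    2. a first classifier is trained on the weak labels and its predictions
       flag implausible sub-paragraphs, whose labels an expert (here: the
       planted truth) replaces;
    3. the final classifiers are trained on the corrected labels and scored
       against truth on a held-out sub-paragraph split.
    """
    config = config or TrainingConfig()
    subs, gold = gold_subparagraphs(reports, truth)
    if table is None:
        texts = [s.text for sub in subs for s in sub.sentences]
        table = hashed_embeddings(vocabulary(texts), dim=config.embedding_dim, seed=config.seed)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subs))
    n_hold = max(1, int(round(holdout_fraction * len(subs))))
    hold_idx = set(order[:n_hold].tolist())
    train_subs = [subs[i] for i in range(len(subs)) if i not in hold_idx]
    train_gold = [gold[i] for i in range(len(subs)) if i not in hold_idx]
    held_subs = [subs[i] for i in range(len(subs)) if i in hold_idx]
    held_gold = [gold[i] for i in range(len(subs)) if i in hold_idx]

    classes = [c.value for c in CATEGORIES]
    generate_programming_labels(train_subs + held_subs, rules)
    programming_f1 = macro_f1(
        _flatten_predictions(held_subs), _flatten_gold(held_gold), classes
    )

    # round 1: model trained on weak labels proposes candidates for review
    first = train_corpus_classifier(train_subs, config, table, model_type="nb_crf")
    classify_corpus(train_subs, first)
    selections = select_for_active_labeling(train_subs)
    selected = {id(sel.sub) for sel in selections}

    # expert labels (the planted truth) for the queried sub-paragraphs;
    # remaining sub-paragraphs keep their programming labels
    generate_programming_labels(train_subs, rules)
    for sub, cats in zip(train_subs, train_gold):
        if id(sub) in selected:
            for sentence, cat in zip(sub.sentences, cats):
                sentence.category = cat

    scores: dict[str, float] = {}
    for model_type in model_types:
        model = train_corpus_classifier(train_subs, config, table, model_type=model_type)
        classify_corpus(held_subs, model)
        scores[model_type] = macro_f1(
            _flatten_predictions(held_subs), _flatten_gold(held_gold), classes
        )
    return ActiveLearningResult(
        programming_macro_f1=programming_f1,
        macro_f1_by_model=scores,
        n_selected=len(selected),
        n_train=len(train_subs),
        n_heldout=len(held_subs),
    )


def interpretation_benchmark(fixtures: InterpFixtures) -> tuple[float, pd.DataFrame]:
    """Classify the planted CNVs and score pCNV-vs-not accuracy vs truth."""
    rows = []
    for idx, cnv in enumerate(fixtures.cnvs):
        _, scores, tier = interpret_cnv(
            cnv,
            fixtures.kbs,
            filters=fixtures.filters,
            scoring=fixtures.scoring,
            rules=fixtures.rules,
            cytobands=fixtures.cytobands,
        )
        planted = fixtures.truth.iloc[idx]
        rows.append(
            {
                "cnv_index": idx,
                "planted_tier": planted["planted_tier"],
                "predicted_tier": tier.value,
                "is_aneuploid": bool(planted["is_aneuploid"]),
                "planted_pcnv": planted["planted_tier"] in ("pathogenic", "likely_pathogenic"),
                "predicted_pcnv": tier.is_pcnv,
                "aneuploid_flag": scores.aneuploid_flag,
            }
        )
    df = pd.DataFrame(rows)
    accuracy = float((df["planted_pcnv"] == df["predicted_pcnv"]).mean())
    return accuracy, df
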