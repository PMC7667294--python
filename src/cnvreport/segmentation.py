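"""Paragraph segmentation: split explanation paragraphs into sub-paragraphs.

One explanation paragraph may cover several variants.  Each sentence is
classified as "begin" (first sentence of one variant's explanation) or
"not_begin" by a TF-IDF + multinomial naive-Bayes model; sub-paragraphs are
then cut at the begin sentences.

Training data construction follows the weak-supervision rule used to mine
the historical corpus: the first sentence of every report is a positive
example, and the remaining sentences of single-variant reports are
negatives (in a single-variant report no later sentence can open a new
explanation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.naive_bayes import MultinomialNB
from sklearn.pipeline import Pipeline

from .models import ClinicalReport, Sentence, SubParagraph
from .text import Tokenizer, default_tokenizer, split_sentences

BEGIN = "begin"
NOT_BEGIN = "not_begin"


@dataclass
class BeginModel:
    """Begin/not-begin sentence classifier."""

    pipeline: Pipeline
    tokenizer: Tokenizer = default_tokenizer

    def predict(self, sentence: Sentence | str) -> str:
        text = sentence.text if isinstance(sentence, Sentence) else sentence
        return self.pipeline.predict([text])[0]

    def predict_many(self, sentences: list[Sentence]) -> list[str]:
        if not sentences:
            return []
        return list(self.pipeline.predict([s.text for s in sentences]))


def build_begin_training_set(
    reports: list[ClinicalReport],
) -> tuple[list[str], list[str]]:
    """(texts, labels) per the first-sentence / single-variant-report rule."""
    texts: list[str] = []
    labels: list[str] = []
    n_single = 0
    for report in reports:
        sentences = split_sentences(report.paragraph)
        if not sentences:
            continue
        texts.append(sentences[0].text)
        labels.append(BEGIN)
        if report.is_single_cnv:
            n_single += 1
            for s in sentences[1:]:
                texts.append(s.text)
                labels.append(NOT_BEGIN)
    if NOT_BEGIN not in labels:
        raise ValueError(
            "no single-variant reports with >1 sentence: cannot build the "
            "negative (not_begin) training class"
        )
    return texts, labels


def train_begin_classifier(
    reports: list[ClinicalReport],
    tokenizer: Tokenizer = default_tokenizer,
) -> BeginModel:
    if len(reports) < 2:
        raise ValueError("need at least two reports to train")
    texts, labels = build_begin_training_set(reports)
    # TF-IDF with library defaults (sublinear off, L2 norm), fit on the
    # constructed training set only.
    pipeline = Pipeline(
        [
            (
                "tfidf",
                TfidfVectorizer(tokenizer=tokenizer, token_pattern=None, lowercase=False),
            ),
            ("nb", MultinomialNB()),
        ]
    )
    pipeline.fit(texts, labels)
    return BeginModel(pipeline=pipeline, tokenizer=tokenizer)


def segment_paragraph(
    sentences: list[Sentence],
    model: BeginModel | None = None,
    predictions: list[str] | None = None,
    report_id: str = "",
) -> list[SubParagraph]:
    """Cut a sentence list into sub-paragraphs at predicted begin sentences.

    Sentence 0 is always forced to begin, so the result is a partition of
    the input: concatenating the sub-paragraphs restores the sentence
    sequence exactly.
    """
    if not sentences:
        raise ValueError("empty sentence list")
    if predictions is None:
        if model is None:
            raise ValueError("need either a model or explicit predictions")
        predictions = model.predict_many(sentences)
    if len(predictions) != len(sentences):
        raise ValueError("predictions/sentences length mismatch")

    subs: list[SubParagraph] = []
    for sent, pred in zip(sentences, predictions):
        is_begin = pred == BEGIN or not subs
        sent.begin_label = BEGIN if is_begin else NOT_BEGIN
        if is_begin:
            subs.append(SubParagraph(sentences=[sent], source_report_id=report_id))
        else:
            subs[-1].sentences.append(sent)
    return subs
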