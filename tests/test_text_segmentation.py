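"""Sentence splitting, tokenization and paragraph segmentation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvreport.models import ClinicalReport, CNVCall
from cnvreport.segmentation import (
    BEGIN,
    NOT_BEGIN,
    build_begin_training_set,
    segment_paragraph,
    train_begin_classifier,
)
from cnvreport.text import default_tokenizer, split_sentences


class TestSplitSentences:
    @pytest.mark.parametrize(
        "paragraph, expected",
        [
            ("A, B. C", ["A", "B", "C"]),
            ("", []),
            ("one clause", ["one clause"]),
            ("a; b, c.", ["a", "b", "c"]),
            ("第一句，第二句。第三句；完", ["第一句", "第二句", "第三句", "完"]),
            # a decimal point is not a sentence boundary
            ("a 1.26 Mb deletion, confirmed.", ["a 1.26 Mb deletion", "confirmed"]),
            (",,..", []),
        ],
    )
    def test_examples(self, paragraph, expected):
        assert [s.text for s in split_sentences(paragraph)] == expected

    def test_indices_contiguous(self):
        sents = split_sentences("a, b, c, d")
        assert [s.index for s in sents] == [0, 1, 2, 3]

    @given(
        st.lists(
            st.text(alphabet="abc xyz", min_size=1).filter(lambda t: t.strip()),
            min_size=1,
            max_size=8,
        )
    )
    def test_token_content_preserved(self, clauses):
        """Joining the split sentences reproduces the paragraph's tokens."""
        paragraph = ", ".join(clauses)
        rejoined = ", ".join(s.text for s in split_sentences(paragraph))
        assert default_tokenizer(rejoined) == default_tokenizer(paragraph)


class TestTokenizer:
    def test_cjk_falls_back_to_characters(self):
        assert default_tokenizer("染色体7缺失") == ["染", "色", "体", "7", "缺", "失"]

    def test_numbers_keep_decimals(self):
        assert default_tokenizer("a 1.26 Mb event") == ["a", "1.26", "mb", "event"]


def _report(report_id, paragraph, n_cnvs=1):
    cnvs = [
        CNVCall("1", 1 + i, 200_000 + i, "duplication") for i in range(n_cnvs)
    ]
    return ClinicalReport(report_id=report_id, cnvs=cnvs, paragraph=paragraph)


class TestBeginClassifier:
    def test_training_set_rule(self):
        """Positives: first sentences; negatives: rest of single-CNV reports."""
        reports = [
            _report("a", "testing found X, details one, details two"),
            _report("b", "testing found Y, more details. testing found Z, tail", n_cnvs=2),
        ]
        texts, labels = build_begin_training_set(reports)
        assert labels.count(BEGIN) == 2
        # only report a's non-first sentences become negatives
        assert [t for t, l in zip(texts, labels) if l == NOT_BEGIN] == [
            "details one",
            "details two",
        ]

    def test_no_single_cnv_reports_errors(self):
        reports = [_report("a", "x, y. z, w", n_cnvs=2)] * 2
        with pytest.raises(ValueError, match="negative"):
            train_begin_classifier(reports)

    def test_planted_phrase_recovered(self, seed1_corpus):
        """Held-out stock begin phrases are recognized almost perfectly."""
        reports, truth = seed1_corpus
        model = train_begin_classifier(reports[:400])
        correct = total = 0
        for report in reports[400:]:
            labels = truth.by_report[report.report_id].begin_labels
            preds = model.predict_many(split_sentences(report.paragraph))
            correct += sum(p == t for p, t in zip(preds, labels))
            total += len(labels)
        assert total > 0
        assert correct / total >= 0.95

    def test_own_first_sentence_is_begin(self):
        reports = [
            _report("a", "testing revealed an event, generic details, more details"),
            _report("b", "testing revealed a change, other details, extra notes"),
        ]
        model = train_begin_classifier(reports)
        assert model.predict("testing revealed an event") == BEGIN


class TestSegmentParagraph:
    def test_predictions_drive_cuts(self):
        sents = split_sentences("a, b, c, d, e")
        subs = segment_paragraph(
            sents, predictions=[BEGIN, NOT_BEGIN, BEGIN, NOT_BEGIN, NOT_BEGIN]
        )
        assert [len(s) for s in subs] == [2, 3]

    def test_first_sentence_forced_begin(self):
        sents = split_sentences("a, b, c")
        subs = segment_paragraph(sents, predictions=[NOT_BEGIN] * 3)
        assert len(subs) == 1
        assert subs[0].sentences[0].begin_label == BEGIN

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            segment_paragraph([], predictions=[])

    @given(st.lists(st.booleans(), min_size=1, max_size=12))
    @settings(max_examples=50)
    def test_partition_property(self, begins):
        """Concatenated sub-paragraphs restore the sentence sequence."""
        paragraph = ", ".join(f"s{i}" for i in range(len(begins)))
        sents = split_sentences(paragraph)
        preds = [BEGIN if b else NOT_BEGIN for b in begins]
        subs = segment_paragraph(sents, predictions=preds)
        flat = [s.text for sub in subs for s in sub.sentences]
        assert flat == [f"s{i}" for i in range(len(begins))]
        n_expected = sum(begins[1:]) + 1
        assert len(subs) == n_expected
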