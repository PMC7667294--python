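"""Programming (weak) labels and active-learning candidate selection.

Programming labels bootstrap corpus classification: an ordered keyword
table assigns each sentence a possibly inaccurate category by
first-matching-rule-wins string matching (e.g. a sentence containing
"literature" is labeled Paper).  Sentences matching no rule fall back to
Basic.

Active learning then flags sub-paragraphs whose predicted label patterns
look linguistically implausible — in practice a syndrome, gene or
literature mention is followed by symptom/recommendation sentences, so
three consecutive sentences rarely carry three different categories — and
routes them to an expert for manual labeling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, TextIO

from .models import Category, Sentence, SubParagraph


@dataclass(frozen=True)
class KeywordRule:
    keyword: str
    category: Category


@dataclass
class KeywordRuleTable:
    """Ordered keyword → category rules; first matching rule wins."""

    rules: list[KeywordRule]
    default_category: Category = Category.BASIC

    def classify(self, text: str) -> Category:
        lower = text.lower()
        for rule in self.rules:
            if rule.keyword.lower() in lower:
                return rule.category
        return self.default_category


#: Default English rule table; mirrors the keyword conventions the
#: synthetic corpus plants.  Order matters: earlier rules win.
DEFAULT_RULES = KeywordRuleTable(
    rules=[
        KeywordRule("trisomy", Category.ANEUPLOID),
        KeywordRule("monosomy", Category.ANEUPLOID),
        KeywordRule("aneuploid", Category.ANEUPLOID),
        KeywordRule("mosaic", Category.ANEUPLOID),
        KeywordRule("syndrome", Category.SYNDROME),
        KeywordRule("haploinsufficien", Category.GENE),
        KeywordRule("triplosensitiv", Category.GENE),
        KeywordRule("gene", Category.GENE),
        KeywordRule("literature", Category.PAPER),
        KeywordRule("pubmed", Category.PAPER),
        KeywordRule("published", Category.PAPER),
        KeywordRule("patient", Category.PATIENT),
        KeywordRule("proband", Category.PATIENT),
    ],
)


def read_rule_table(source: str | Path | TextIO) -> KeywordRuleTable:
    """Two-column TSV: keyword<TAB>category, in priority order."""
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_rule_table(fh)
    rules = [
        KeywordRule(row[0], Category(row[1]))
        for row in csv.reader(source, delimiter="\t")
        if row and not row[0].startswith("#")
    ]
    if not rules:
        raise ValueError("empty rule table")
    return KeywordRuleTable(rules=rules)


def generate_programming_labels(
    subs: Iterable[SubParagraph], rules: KeywordRuleTable = DEFAULT_RULES
) -> list[SubParagraph]:
    """Assign every sentence a weak category label in place; returns subs."""
    subs = list(subs)
    for sub in subs:
        for sentence in sub.sentences:
            sentence.category = rules.classify(sentence.text)
    return subs


@dataclass(frozen=True)
class ActiveSelection:
    sub: SubParagraph
    trigger_window: bool  # 3 consecutive sentences, 3 distinct categories
    trigger_diversity: bool  # > 3 distinct categories in the sub-paragraph

    @property
    def selected(self) -> bool:
        return self.trigger_window or self.trigger_diversity


def _categories(sub: SubParagraph) -> list[Category]:
    cats = []
    for s in sub.sentences:
        if s.category is None:
            raise ValueError("sentence without a predicted category")
        cats.append(Category(s.category))
    return cats


def select_for_active_labeling(
    subs: Iterable[SubParagraph],
    combine: Literal["or", "and"] = "or",
) -> list[ActiveSelection]:
    """Flag sub-paragraphs whose label pattern warrants expert review.

    Two triggers are evaluated per sub-paragraph and reported separately:
    a window of three consecutive sentences with three distinct categories,
    and more than three distinct categories overall.  By default either
    trigger selects (the more inclusive reading); ``combine="and"`` requires
    both.
    """
    out = []
    for sub in subs:
        cats = _categories(sub)
        window = any(
            len({cats[i], cats[i + 1], cats[i + 2]}) == 3
            for i in range(len(cats) - 2)
        )
        diversity = len(set(cats)) > 3
        sel = ActiveSelection(sub=sub, trigger_window=window, trigger_diversity=diversity)
        keep = (window or diversity) if combine == "or" else (window and diversity)
        if keep:
            out.append(sel)
    return out
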