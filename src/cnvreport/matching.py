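"""CNV ↔ sub-paragraph matching by keyword relation scores.

Each candidate pair gets a weighted sum of four binary keyword matches:

    score = 5*chr_score + 2*type_score + cyto_score + length_score

where each component is 1 iff the CNV's rendered keyword (chromosome token,
variant-type word, cytoband label, formatted length) occurs in the
sub-paragraph text.  The chromosome carries the largest weight because it is
the least ambiguous of the four.  Each CNV is independently assigned the
argmax sub-paragraph; equal scores break to the lowest sub-paragraph index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .cytoband import CytobandTable, cytoband_label
from .models import CNVCall, RelationScore, SubParagraph, VariationType

TYPE_KEYWORDS: dict[VariationType, str] = {
    VariationType.HOMOZYGOUS_DELETION: "deletion",
    VariationType.HETEROZYGOUS_DELETION: "deletion",
    VariationType.DUPLICATION: "duplication",
    VariationType.TRIPLICATION: "triplication",
}

#: How a chromosome may be written in report text; {c} is the chromosome
#: name and the trailing guard stops "chr1" matching "chr11".
CHROM_PATTERNS: tuple[str, ...] = (
    r"chr\s*{c}(?![\dXY])",
    r"chromosome\s+{c}(?![\dXY])",
    r"(?<![\dXY]){c}号",
)


def render_length(length_bp: int) -> str:
    """Render a CNV length the way report text prints it.

    >= 1 Mb: megabases with at most two decimals and trailing zeros trimmed
    ("50 Mb", "1.26 Mb"); below 1 Mb: integer kilobases ("480 Kb").
    """
    if length_bp >= 1_000_000:
        mb = length_bp / 1_000_000
        text = f"{mb:.2f}".rstrip("0").rstrip(".")
        return f"{text} Mb"
    return f"{round(length_bp / 1000)} Kb"


def chromosome_regex(chrom: str, patterns: tuple[str, ...] = CHROM_PATTERNS) -> re.Pattern[str]:
    alts = "|".join(p.format(c=re.escape(chrom)) for p in patterns)
    return re.compile(alts, flags=re.IGNORECASE)


def relation_score(
    cnv: CNVCall,
    sub: SubParagraph | str,
    cytobands: CytobandTable,
    chrom_patterns: tuple[str, ...] = CHROM_PATTERNS,
) -> RelationScore:
    """Score how well a sub-paragraph's text describes a CNV."""
    text = sub if isinstance(sub, str) else sub.text
    lower = text.lower()

    chr_score = 1 if chromosome_regex(cnv.chrom, chrom_patterns).search(text) else 0
    type_score = 1 if TYPE_KEYWORDS[cnv.variation_type] in lower else 0
    cyto = cytoband_label(cnv, cytobands)
    cyto_score = 1 if cyto.lower() in lower else 0
    length_score = 1 if render_length(cnv.length_bp).lower() in lower else 0
    return RelationScore(
        chr_score=chr_score,
        type_score=type_score,
        cyto_score=cyto_score,
        length_score=length_score,
    )


def argmax_first_tie(rows: list[list[int | float]]) -> dict[int, int]:
    """Row-wise argmax with ties broken to the lowest column index."""
    assignment: dict[int, int] = {}
    for i, row in enumerate(rows):
        best_j = 0
        for j, v in enumerate(row):
            if v > row[best_j]:
                best_j = j
        assignment[i] = best_j
    return assignment


def score_matrix(
    cnvs: list[CNVCall],
    subs: list[SubParagraph],
    cytobands: CytobandTable,
) -> list[list[int]]:
    return [
        [relation_score(cnv, sub, cytobands).total for sub in subs] for cnv in cnvs
    ]


def match_cnvs(
    cnvs: list[CNVCall],
    subs: list[SubParagraph],
    cytobands: CytobandTable,
) -> dict[int, int]:
    """Assign each CNV its best-scoring sub-paragraph (first on ties).

    The assignment is many-to-one: every CNV is scored independently, so two
    CNVs may share a sub-paragraph.  Matched indices are also written onto
    the sub-paragraphs (last writer wins on shared subs).
    """
    if not subs:
        raise ValueError("no sub-paragraphs to match against")
    assignment = argmax_first_tie(score_matrix(cnvs, subs, cytobands))
    for cnv_idx, sub_idx in assignment.items():
        subs[sub_idx].matched_cnv_index = cnv_idx
    return assignment
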