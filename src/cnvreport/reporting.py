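"""Diagnostic report composition.

Each reported variant gets one block:

* **basic description** — cytogenetic location, variation type and CNV
  length, rendered so the text contains exactly the four keywords the
  CNV ↔ paragraph matcher looks for (a report block always relates to its
  own CNV with the maximal relation score);
* **special explanation** — for pathogenic/likely-pathogenic CNVs, the
  syndrome, gene-dosage and literature corpus sentences from the knowledge
  bases (in that order) followed by a clinical-significance statement; for
  whole-chromosome events, the Aneuploid knowledge-base description
  verbatim; for benign or VOUS CNVs, a fixed database-citation template
  sentence.

Benign blocks are generated but flagged suppressed by default, since
geneticists do not generally report them.  Report generation is pure:
identical inputs yield byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cytoband import CytobandTable, cytoband_label
from .interpretation import Annotation
from .knowledge_bases import KnowledgeBaseSet
from .matching import TYPE_KEYWORDS, render_length
from .models import CNVCall, FiveTier

#: Locale template strings.  {classification} is substituted with the
#: reported class.  The zh entry is a translation of the en sentence.
TEMPLATES = {
    "en": {
        "benign_vous": (
            "according to DGV, DECIPHER, OMIM, UCSC and PubMed databases and "
            "ACMG guidelines, this is a {classification} CNV"
        ),
        "significance": "this CNV is classified as {classification}",
    },
    "zh": {
        "benign_vous": (
            "根据DGV、DECIPHER、OMIM、UCSC和PubMed数据库及ACMG指南，"
            "该拷贝数变异为{classification}"
        ),
        "significance": "该拷贝数变异分类为{classification}",
    },
}


@dataclass
class VariantBlock:
    cnv: CNVCall
    basic_description: str
    special_explanation: str
    reported_classification: str  # pathogenic | likely_pathogenic | VOUS | benign
    suppressed: bool = False
    corpus_sources: tuple[str, ...] = ()

    @property
    def text(self) -> str:
        return f"{self.basic_description}, {self.special_explanation}"

    def to_dict(self) -> dict:
        return {
            "chrom": self.cnv.chrom,
            "start": self.cnv.start,
            "end": self.cnv.end,
            "variation_type": self.cnv.variation_type.value,
            "basic_description": self.basic_description,
            "special_explanation": self.special_explanation,
            "reported_classification": self.reported_classification,
            "suppressed": self.suppressed,
            "corpus_sources": list(self.corpus_sources),
        }


@dataclass
class DiagnosticReport:
    sample_id: str
    sample_type: str
    blocks: list[VariantBlock]
    review_status: str = "pending_review"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "sample_type": self.sample_type,
            "review_status": self.review_status,
            "variants": [b.to_dict() for b in self.blocks],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)

    def to_text(self, include_suppressed: bool = False) -> str:
        lines = [f"Sample {self.sample_id} ({self.sample_type}) — {self.review_status}"]
        for block in self.blocks:
            if block.suppressed and not include_suppressed:
                continue
            lines.append(f"[{block.reported_classification}] {block.text}")
        return "\n".join(lines)


def basic_description(cnv: CNVCall, cytobands: CytobandTable) -> str:
    """Band, type and length rendered with all four matching keywords."""
    band = cytoband_label(cnv, cytobands)
    type_word = TYPE_KEYWORDS[cnv.variation_type]
    length = render_length(cnv.length_bp)
    return (
        f"a {length} {type_word} on chromosome {cnv.chrom} "
        f"at cytoband {band} ({cnv.chrom}{band})"
    )


def _collect_corpus(annotation: Annotation) -> tuple[list[str], list[str]]:
    """(ordered corpus sentences, source tags) for a pathogenic call."""
    texts: list[str] = []
    sources: list[str] = []
    for store in ("syndrome", "gene", "paper"):
        for hit in annotation.hits[store]:
            corpus = getattr(hit.record, "corpus", "")
            if corpus:
                texts.append(corpus)
                sources.append(store)
    return texts, sources


def compose_report(
    sample_id: str,
    calls: list[CNVCall],
    classifications: list[FiveTier],
    kbs: KnowledgeBaseSet,
    cytobands: CytobandTable,
    annotations: list[Annotation] | None = None,
    templates: dict | None = None,
    locale: str = "en",
    suppress_benign: bool = True,
) -> DiagnosticReport:
    """Compose a structured diagnostic report for one sample.

    ``annotations`` (from the interpretation layer) supply the evidence
    corpus for pathogenic calls; a pathogenic call whose evidence corpus is
    empty and that has no Aneuploid description raises, because a
    pathogenic classification without citable evidence is an
    interpretation/reporting inconsistency.
    """
    if len(calls) != len(classifications):
        raise ValueError("calls and classifications must align")
    tmpl = (templates or TEMPLATES)[locale]
    blocks: list[VariantBlock] = []

    for i, (cnv, tier) in enumerate(zip(calls, classifications)):
        annotation = annotations[i] if annotations is not None else None
        reported = tier.reported
        desc = basic_description(cnv, cytobands)
        whole = annotation.whole_chromosome if annotation is not None else False
        sources: tuple[str, ...] = ()

        if whole and tier.is_pcnv:
            event = "gain" if cnv.variation_type.is_gain else "loss"
            records = kbs.aneuploid.query(cnv.chrom, event)
            if records:
                explanation = records[0].description_corpus
                sources = ("aneuploid",)
            else:
                explanation = (
                    f"whole-chromosome {event} of chromosome {cnv.chrom}, "
                    + tmpl["significance"].format(classification=reported)
                )
                sources = ("derived",)
        elif tier.is_pcnv:
            texts, src = _collect_corpus(annotation) if annotation is not None else ([], [])
            if not texts:
                raise ValueError(
                    f"pathogenic call {cnv.chrom}:{cnv.start}-{cnv.end} has an "
                    "empty evidence corpus: classification/evidence inconsistency"
                )
            explanation = (
                ", ".join(texts)
                + ", "
                + tmpl["significance"].format(classification=reported)
            )
            sources = tuple(src)
        else:
            explanation = tmpl["benign_vous"].format(classification=reported)

        blocks.append(
            VariantBlock(
                cnv=cnv,
                basic_description=desc,
                special_explanation=explanation,
                reported_classification=reported,
                suppressed=suppress_benign and reported == FiveTier.BENIGN.value,
                corpus_sources=sources,
            )
        )
    sample_type = calls[0].sample_type.value if calls else "prenatal"
    return DiagnosticReport(sample_id=sample_id, sample_type=sample_type, blocks=blocks)
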