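"""Annotation, evidence scoring and five-tier classification of CNV calls.

Three layers, each reviewable:

1. **Annotation** — query every knowledge-base store for records
   intersecting the call, attach exact overlap fractions, and apply the
   configured retrieval filters (minimum reciprocal overlaps, polymorphism
   study size).  Hits inside incomplete-penetrance regions stay visible in
   the annotation but are excluded from scoring.
2. **Interpretation** — reduce surviving hits to numeric evidence scores.
   The overlap-fraction semantics (overlap_db = overlap / record length,
   overlap_query = overlap / call length) and the evidence sources
   (polymorphism frequency and study sample size, syndrome/gene dosage
   mechanism, published P/LP case counts) are fixed; every numeric
   threshold or weight is a named config default, overridable.
3. **Classification** — a deterministic rule ladder mapping scores to the
   ACMG five-tier scale.  Whole-chromosome events (aneuploidy, mosaicism)
   are always pathogenic.  Patient-store hits are display-only and carry no
   score, so no path exists from a patient record to the final call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .cytoband import CytobandTable, is_whole_chromosome_event
from .knowledge_bases import (
    GeneRecord,
    KnowledgeBaseSet,
    PolymorphismRecord,
    Region,
    SyndromeRecord,
)
from .models import CNVCall, FiveTier, Gender, VariationType


@dataclass(frozen=True)
class OverlapFractions:
    overlap_bp: int
    overlap_db: float  # overlap / KB record length
    overlap_query: float  # overlap / queried CNV length


def overlap_fractions(query: CNVCall | Region, record_region: Region) -> OverlapFractions:
    """Exact reciprocal overlap between a call and a KB record region.

    Different chromosomes (or no intersection) yield (0, 0.0, 0.0).
    """
    q_chrom = query.chrom
    if q_chrom != record_region.chrom:
        return OverlapFractions(0, 0.0, 0.0)
    lo = max(query.start, record_region.start)
    hi = min(query.end, record_region.end)
    overlap = hi - lo + 1
    if overlap <= 0:
        return OverlapFractions(0, 0.0, 0.0)
    q_len = query.end - query.start + 1
    return OverlapFractions(overlap, overlap / record_region.length_bp, overlap / q_len)


@dataclass(frozen=True)
class AnnotationFilterConfig:
    """Retrieval filters applied per store during annotation."""

    min_overlap_db: dict[str, float] = field(
        default_factory=lambda: {
            "polymorphism": 0.0,
            "syndrome": 0.5,
            "gene": 0.5,
            "paper": 0.0,
            "patient": 0.0,
        }
    )
    min_overlap_query: dict[str, float] = field(
        default_factory=lambda: {
            "polymorphism": 0.0,
            "syndrome": 0.0,
            "gene": 0.0,
            "paper": 0.5,
            "patient": 0.0,
        }
    )
    min_polymorphism_sample_size: int = 1000
    min_polymorphism_frequency: float = 0.0
    #: recurrent regions with incomplete penetrance: annotated, never scored
    incomplete_penetrance_regions: tuple[Region, ...] = ()
    whole_chromosome_fraction: float = 0.99


@dataclass
class AnnotatedHit:
    store: str
    record: Any
    fractions: OverlapFractions
    excluded: bool = False  # True for incomplete-penetrance hits
    note: str = ""

    def to_dict(self) -> dict:
        from .knowledge_bases import _record_to_row  # shared field rendering

        return {
            "store": self.store,
            "record": _record_to_row(self.record),
            "overlap_bp": self.fractions.overlap_bp,
            "overlap_db": self.fractions.overlap_db,
            "overlap_query": self.fractions.overlap_query,
            "excluded": self.excluded,
            "note": self.note,
        }


@dataclass
class Annotation:
    cnv: CNVCall
    hits: dict[str, list[AnnotatedHit]]
    whole_chromosome: bool = False
    aneuploidy_descriptor: str | None = None
    hemizygous: bool = False

    def to_dict(self) -> dict:
        return {
            "cnv": {
                "chrom": self.cnv.chrom,
                "start": self.cnv.start,
                "end": self.cnv.end,
                "variation_type": self.cnv.variation_type.value,
                "gender": self.cnv.gender.value,
                "sample_type": self.cnv.sample_type.value,
            },
            "whole_chromosome": self.whole_chromosome,
            "aneuploidy_descriptor": self.aneuploidy_descriptor,
            "hemizygous": self.hemizygous,
            "hits": {s: [h.to_dict() for h in hs] for s, hs in self.hits.items()},
        }


def _in_blocklist(region: Region, blocklist: tuple[Region, ...]) -> bool:
    for b in blocklist:
        if (
            region.chrom == b.chrom
            and region.start >= b.start
            and region.end <= b.end
        ):
            return True
    return False


def annotate_cnv(
    cnv: CNVCall,
    kbs: KnowledgeBaseSet,
    filters: AnnotationFilterConfig | None = None,
    cytobands: CytobandTable | None = None,
) -> Annotation:
    """Retrieve and filter KB evidence for one call."""
    filters = filters or AnnotationFilterConfig()
    hits: dict[str, list[AnnotatedHit]] = {s: [] for s in ("polymorphism", "syndrome", "gene", "paper", "patient")}

    for store_name in hits:
        store = kbs.store(store_name)
        for record, _overlap in store.query(cnv.chrom, cnv.start, cnv.end):
            frac = overlap_fractions(cnv, record.region)
            if frac.overlap_db < filters.min_overlap_db.get(store_name, 0.0):
                continue
            if frac.overlap_query < filters.min_overlap_query.get(store_name, 0.0):
                continue
            note = ""
            if store_name == "polymorphism":
                if record.sample_size < filters.min_polymorphism_sample_size:
                    continue
                if record.frequency < filters.min_polymorphism_frequency:
                    continue
            excluded = _in_blocklist(record.region, filters.incomplete_penetrance_regions)
            if excluded:
                note = "incomplete-penetrance region: annotated only"
            hits[store_name].append(
                AnnotatedHit(store=store_name, record=record, fractions=frac, excluded=excluded, note=note)
            )

    whole, descriptor = (False, None)
    if cytobands is not None and cnv.chrom in cytobands.chroms:
        whole, descriptor = is_whole_chromosome_event(
            cnv, cytobands, filters.whole_chromosome_fraction
        )

    # single-copy X in a male is hemizygous, not a heterozygous-deletion
    # mismatch; flagged so reviewers and scoring see the semantics
    hemizygous = (
        cnv.chrom in ("X", "Y")
        and cnv.gender is Gender.MALE
        and cnv.variation_type is VariationType.HETEROZYGOUS_DELETION
    )
    return Annotation(
        cnv=cnv,
        hits=hits,
        whole_chromosome=whole,
        aneuploidy_descriptor=descriptor,
        hemizygous=hemizygous,
    )


@dataclass(frozen=True)
class EvidenceScores:
    benign_score: float = 0.0
    syndrome_score: float = 0.0
    gene_score: float = 0.0
    paper_score: float = 0.0
    aneuploid_flag: bool = False
    patient_annotations: tuple[str, ...] = ()  # display-only, never scored

    def to_dict(self) -> dict:
        return {
            "benign_score": self.benign_score,
            "syndrome_score": self.syndrome_score,
            "gene_score": self.gene_score,
            "paper_score": self.paper_score,
            "aneuploid_flag": self.aneuploid_flag,
            "patient_annotations": list(self.patient_annotations),
        }


@dataclass(frozen=True)
class ScoringConfig:
    #: gene hits need at least this overlap_db to count one point
    gene_min_overlap_db: float = 0.5


def _mechanism_matches(record: SyndromeRecord | GeneRecord, vtype: VariationType) -> bool:
    if isinstance(record, SyndromeRecord):
        mech = record.dosage_mechanism
        if mech == "both":
            return True
        return mech == "deletion" if vtype.is_loss else mech == "duplication"
    sens = record.dosage_sensitivity
    if sens == "both":
        return True
    if sens == "none":
        return False
    return sens == "haploinsufficient" if vtype.is_loss else sens == "triplosensitive"


def evidence_scores(
    annotation: Annotation, config: ScoringConfig | None = None
) -> EvidenceScores:
    """Reduce an annotation to numeric evidence.

    All reductions are monotone: enlarging an overlap, frequency, study
    size or case count can never decrease a score.
    """
    config = config or ScoringConfig()
    vtype = annotation.cnv.variation_type

    benign = 0.0
    for hit in annotation.hits["polymorphism"]:
        if hit.excluded:
            continue
        rec: PolymorphismRecord = hit.record
        benign = max(benign, rec.frequency * hit.fractions.overlap_query)

    syndrome = 0.0
    for hit in annotation.hits["syndrome"]:
        if hit.excluded or not _mechanism_matches(hit.record, vtype):
            continue
        syndrome = max(syndrome, hit.fractions.overlap_db)

    gene = 0.0
    for hit in annotation.hits["gene"]:
        if hit.excluded or not _mechanism_matches(hit.record, vtype):
            continue
        if hit.fractions.overlap_db >= config.gene_min_overlap_db:
            gene += 1.0

    paper = 0.0
    for hit in annotation.hits["paper"]:
        if hit.excluded:
            continue
        paper += hit.record.plp_case_count

    patient = tuple(
        f"{h.record.region.chrom}:{h.record.region.start}-{h.record.region.end} "
        f"{h.record.phenotype}".strip()
        for h in annotation.hits["patient"]
    )
    return EvidenceScores(
        benign_score=benign,
        syndrome_score=syndrome,
        gene_score=gene,
        paper_score=paper,
        aneuploid_flag=annotation.whole_chromosome,
        patient_annotations=patient,
    )


@dataclass(frozen=True)
class ClassificationRuleConfig:
    """The rule ladder's named thresholds (all overridable)."""

    syndrome_pathogenic: float = 0.8  # overlap_db of a mechanism-matched syndrome
    syndrome_likely: float = 0.5
    gene_pathogenic: float = 2.0  # count of dosage-matched sensitive genes
    gene_likely: float = 1.0
    paper_pathogenic: float = 10.0  # published P/LP cases
    paper_likely: float = 3.0
    benign_frequency: float = 0.01  # population frequency x overlap_query


def classify_variant(
    scores: EvidenceScores, rules: ClassificationRuleConfig | None = None
) -> FiveTier:
    """Deterministic five-tier call from evidence scores.

    Ladder: aneuploidy → pathogenic; strong syndrome/gene/paper evidence →
    pathogenic; moderate → likely pathogenic; common polymorphism with no
    pathogenic evidence → benign; otherwise VOUS.  (Likely benign exists in
    the scale but the ladder reports benign for both, matching reporting
    practice.)
    """
    rules = rules or ClassificationRuleConfig()
    if scores.aneuploid_flag:
        return FiveTier.PATHOGENIC
    if (
        scores.syndrome_score >= rules.syndrome_pathogenic
        or scores.gene_score >= rules.gene_pathogenic
        or scores.paper_score >= rules.paper_pathogenic
    ):
        return FiveTier.PATHOGENIC
    if (
        scores.syndrome_score >= rules.syndrome_likely
        or scores.gene_score >= rules.gene_likely
        or scores.paper_score >= rules.paper_likely
    ):
        return FiveTier.LIKELY_PATHOGENIC
    if scores.benign_score >= rules.benign_frequency:
        return FiveTier.BENIGN
    return FiveTier.VOUS


def interpret_cnv(
    cnv: CNVCall,
    kbs: KnowledgeBaseSet,
    filters: AnnotationFilterConfig | None = None,
    scoring: ScoringConfig | None = None,
    rules: ClassificationRuleConfig | None = None,
    cytobands: CytobandTable | None = None,
) -> tuple[Annotation, EvidenceScores, FiveTier]:
    """Full annotate → score → classify pass for one call."""
    annotation = annotate_cnv(cnv, kbs, filters, cytobands)
    scores = evidence_scores(annotation, scoring)
    tier = classify_variant(scores, rules)
    return annotation, scores, tier
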