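"""Seeded synthetic fixtures with ground truth.

The proprietary historical corpus behind this pipeline is unavailable, so
every stage is exercised on generated data instead:

* :func:`simulate_corpus` emits clinical-report-shaped records whose
  explanation paragraphs are built from per-variant sub-paragraphs, each
  embedding the variant's chromosome / type / cytoband / length keywords
  (subject to independent per-keyword dropout) plus category-bearing body
  sentences.  Ground truth records the begin labels, the CNV ↔
  sub-paragraph mapping and every sentence's category.
* :func:`simulate_interpretation_fixtures` co-designs knowledge-base
  records and CNV calls so the default rule ladder recovers the planted
  five-tier truth, with decoy evidence (underpowered studies, mismatched
  dosage mechanisms, incomplete-penetrance regions) planted to stay
  inert.

The prose is English pseudo-clinical text: tokenizer-neutral, with none of
the linguistic richness of real reports.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytoband import CytobandRecord, CytobandTable
from .interpretation import (
    AnnotationFilterConfig,
    ClassificationRuleConfig,
    ScoringConfig,
)
from .knowledge_bases import (
    AneuploidRecord,
    GeneRecord,
    KnowledgeBaseSet,
    PaperRecord,
    PatientRecord,
    PolymorphismRecord,
    Region,
    SyndromeRecord,
)
from .matching import render_length
from .models import (
    Category,
    ClinicalReport,
    CNVCall,
    FiveTier,
    Gender,
    SampleType,
    VariationType,
)

# ---------------------------------------------------------------------------
# toy genome

_P_BANDS = ("p15", "p14", "p13", "p12", "p11")
_Q_BANDS = ("q11", "q21", "q22", "q31", "q32", "q33")


def toy_cytobands() -> CytobandTable:
    """A deterministic toy genome: 22 autosomes + X + Y with named bands."""
    records = []
    lengths: dict[str, int] = {}
    for i in range(1, 23):
        lengths[str(i)] = (250 - 8 * (i - 1)) * 1_000_000
    lengths["X"] = 155_000_000
    lengths["Y"] = 59_000_000
    for chrom, length in lengths.items():
        p_len = int(round(0.4 * length / 100_000) * 100_000)
        q_len = length - p_len
        pos = 0
        for j, name in enumerate(_P_BANDS):
            end = p_len if j == len(_P_BANDS) - 1 else pos + p_len // len(_P_BANDS)
            stain = "acen" if name == "p11" else ("gneg" if j % 2 == 0 else "gpos50")
            records.append(CytobandRecord(chrom, pos, end, name, stain))
            pos = end
        for j, name in enumerate(_Q_BANDS):
            end = length if j == len(_Q_BANDS) - 1 else pos + q_len // len(_Q_BANDS)
            stain = "acen" if name == "q11" else ("gneg" if j % 2 == 0 else "gpos50")
            records.append(CytobandRecord(chrom, pos, end, name, stain))
            pos = end
    return CytobandTable(records)


# ---------------------------------------------------------------------------
# corpus simulation

#: Per-category trigger keywords (recognized by the default rule table) and
#: auxiliary vocabulary (correlated with the category but carrying no rule).
_TRIGGERS: dict[Category, tuple[str, ...]] = {
    Category.SYNDROME: ("syndrome",),
    Category.GENE: ("gene", "haploinsufficiency"),
    Category.PAPER: ("literature", "published"),
    Category.PATIENT: ("patient", "proband"),
    Category.ANEUPLOID: ("trisomy", "monosomy", "mosaic"),
}
_AUX: dict[Category, tuple[str, ...]] = {
    Category.SYNDROME: ("microdeletion", "dysmorphic", "craniofacial", "recurrent", "developmental"),
    Category.GENE: ("dosage", "sensitive", "coding", "expression", "transcript"),
    Category.PAPER: ("cohort", "reported", "studies", "authors", "journal"),
    Category.PATIENT: ("phenotype", "clinical", "features", "ultrasound", "counseling"),
    Category.BASIC: ("copy", "number", "segment", "interval", "coordinates"),
    Category.ANEUPLOID: ("karyotype", "whole", "extra", "euploid", "nondisjunction"),
}
_FILLER = ("the", "of", "with", "was", "this", "and", "for", "further", "overall")
_BEGIN_OPENERS = (
    "sample analysis revealed",
    "testing identified",
    "sequencing detected",
)

_TYPE_WORDS = {
    VariationType.HOMOZYGOUS_DELETION: "deletion",
    VariationType.HETEROZYGOUS_DELETION: "deletion",
    VariationType.DUPLICATION: "duplication",
    VariationType.TRIPLICATION: "triplication",
}


@dataclass(frozen=True)
class CorpusSimConfig:
    n_reports: int = 500
    multi_cnv_fraction: float = 0.19  # share of reports with >1 variant
    max_cnvs_per_report: int = 3
    body_sentences_range: tuple[int, int] = (2, 5)
    #: body-sentence category mixture for CNV sub-paragraphs
    category_mixture: dict[Category, float] = field(
        default_factory=lambda: {
            Category.SYNDROME: 0.25,
            Category.GENE: 0.20,
            Category.PAPER: 0.20,
            Category.PATIENT: 0.15,
            Category.BASIC: 0.20,
        }
    )
    aneuploid_variant_fraction: float = 0.12
    keyword_dropout: float = 0.15
    distractor_insertion: float = 0.08
    #: clinical prose continues a topic over consecutive sentences: a
    #: category mention is often followed by generic symptom/recommendation
    #: sentences whose category is carried by context, not keywords
    continuation_fraction: float = 0.15
    seed: int = 1

    def validate(self) -> None:
        for name in ("multi_cnv_fraction", "aneuploid_variant_fraction", "keyword_dropout", "distractor_insertion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.category_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"category mixture sums to {total}, expected 1")
        if all(v == 0 for v in self.category_mixture.values()):
            raise ValueError("degenerate category mixture")


@dataclass
class ReportTruth:
    begin_labels: list[str]
    sub_sizes: list[int]
    categories: list[Category]  # per sentence, paragraph order
    cnv_to_sub: dict[int, int]

    @property
    def sub_spans(self) -> list[tuple[int, int]]:
        spans, pos = [], 0
        for size in self.sub_sizes:
            spans.append((pos, pos + size))
            pos += size
        return spans


@dataclass
class CorpusTruth:
    by_report: dict[str, ReportTruth]

    @property
    def n_pairs(self) -> int:
        return sum(len(t.cnv_to_sub) for t in self.by_report.values())


def _random_cnv(
    rng: np.random.Generator,
    chrom: str,
    cytobands: CytobandTable,
    aneuploid: bool,
    gender: Gender = Gender.UNKNOWN,
    sample_type: SampleType = SampleType.PRENATAL,
) -> CNVCall:
    length = cytobands.chrom_length(chrom)
    types = [
        VariationType.HETEROZYGOUS_DELETION,
        VariationType.DUPLICATION,
        VariationType.HOMOZYGOUS_DELETION,
        VariationType.TRIPLICATION,
    ]
    vtype = types[int(rng.choice(len(types), p=[0.45, 0.4, 0.08, 0.07]))]
    if aneuploid:
        return CNVCall(chrom, 1, length, vtype, gender, sample_type)
    size = int(round(np.exp(rng.uniform(np.log(150_000), np.log(30_000_000))) / 10_000) * 10_000)
    size = min(size, length - 2_000_000)
    start = int(rng.integers(1, length - size))
    return CNVCall(chrom, start, start + size - 1, vtype, gender, sample_type)


def _begin_sentence(
    rng: np.random.Generator, cnv: CNVCall, cytobands: CytobandTable, dropout: float
) -> str:
    from .cytoband import cytoband_label

    opener = _BEGIN_OPENERS[rng.integers(len(_BEGIN_OPENERS))]
    size = f"a {render_length(cnv.length_bp)}" if rng.random() >= dropout else "a sizeable"
    type_word = _TYPE_WORDS[cnv.variation_type] if rng.random() >= dropout else "imbalance"
    chrom_phrase = (
        f"on chromosome {cnv.chrom}" if rng.random() >= dropout else "on one autosome"
    )
    cyto_phrase = (
        f"at cytoband {cytoband_label(cnv, cytobands)}"
        if rng.random() >= dropout
        else "at an interior band"
    )
    return f"{opener} {size} {type_word} {chrom_phrase} {cyto_phrase}"


def _body_sentence(rng: np.random.Generator, category: Category, config: CorpusSimConfig) -> str:
    words: list[str] = []
    if category is not Category.BASIC and rng.random() >= config.keyword_dropout:
        triggers = _TRIGGERS[category]
        words.append(triggers[rng.integers(len(triggers))])
    aux = list(_AUX[category])
    rng.shuffle(aux)
    words.extend(aux[:2])
    filler = list(_FILLER)
    rng.shuffle(filler)
    words.extend(filler[: rng.integers(2, 4)])
    rng.shuffle(words)
    if words and rng.random() < config.distractor_insertion:
        others = [c for c in _TRIGGERS if c is not category]
        other = others[rng.integers(len(others))]
        trig = _TRIGGERS[other]
        words.append(trig[rng.integers(len(trig))])
    return " ".join(words)


def _continuation_sentence(rng: np.random.Generator, category: Category) -> str:
    words = list(_FILLER)
    rng.shuffle(words)
    words = words[: rng.integers(3, 6)]
    if rng.random() < 0.5:
        aux = _AUX[category]
        words.insert(int(rng.integers(len(words) + 1)), aux[rng.integers(len(aux))])
    return " ".join(words)


def simulate_corpus(config: CorpusSimConfig | None = None) -> tuple[list[ClinicalReport], CorpusTruth]:
    """Generate a synthetic report corpus with full ground truth."""
    config = config or CorpusSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cytobands = toy_cytobands()
    chroms = cytobands.chroms

    cats = list(config.category_mixture)
    probs = np.array([config.category_mixture[c] for c in cats])
    probs = probs / probs.sum()

    reports: list[ClinicalReport] = []
    truth: dict[str, ReportTruth] = {}
    for r in range(config.n_reports):
        report_id = f"R{r:05d}"
        n_cnvs = 1
        if rng.random() < config.multi_cnv_fraction:
            n_cnvs = int(rng.integers(2, config.max_cnvs_per_report + 1))
        report_chroms = rng.choice(chroms, size=n_cnvs, replace=False)
        sample_type = SampleType.PRENATAL if rng.random() < 0.5 else SampleType.POC
        gender = Gender.FEMALE if rng.random() < 0.5 else Gender.MALE

        cnvs: list[CNVCall] = []
        sub_texts: list[list[str]] = []
        begin_labels: list[str] = []
        categories: list[Category] = []
        sub_sizes: list[int] = []
        for chrom in report_chroms:
            aneuploid = rng.random() < config.aneuploid_variant_fraction
            cnv = _random_cnv(rng, str(chrom), cytobands, aneuploid, gender, sample_type)
            cnvs.append(cnv)
            sentences = [_begin_sentence(rng, cnv, cytobands, config.keyword_dropout)]
            sent_cats = [Category.BASIC]
            n_body = int(rng.integers(*config.body_sentences_range))
            for j in range(n_body):
                if j > 0 and rng.random() < config.continuation_fraction:
                    # topic continuation: category inherited from the
                    # previous sentence, wording mostly generic
                    cat = sent_cats[-1]
                    sentences.append(_continuation_sentence(rng, cat))
                    sent_cats.append(cat)
                    continue
                if aneuploid:
                    cat = Category.ANEUPLOID if rng.random() < 0.6 else (
                        Category.PATIENT if rng.random() < 0.5 else Category.BASIC
                    )
                else:
                    cat = cats[int(rng.choice(len(cats), p=probs))]
                sentences.append(_body_sentence(rng, cat, config))
                sent_cats.append(cat)
            sub_texts.append(sentences)
            begin_labels.extend(["begin"] + ["not_begin"] * (len(sentences) - 1))
            categories.extend(sent_cats)
            sub_sizes.append(len(sentences))

        paragraph = ". ".join(", ".join(s) for s in sub_texts) + "."
        reports.append(
            ClinicalReport(
                report_id=report_id,
                cnvs=cnvs,
                paragraph=paragraph,
                sample_type=sample_type,
                gender=gender,
            )
        )
        truth[report_id] = ReportTruth(
            begin_labels=begin_labels,
            sub_sizes=sub_sizes,
            categories=categories,
            cnv_to_sub={i: i for i in range(n_cnvs)},
        )
    return reports, CorpusTruth(by_report=truth)


# ---------------------------------------------------------------------------
# interpretation fixtures


@dataclass(frozen=True)
class InterpSimConfig:
    n_cnvs: int = 200
    tier_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "pathogenic": 0.20,
            "likely_pathogenic": 0.12,
            "VOUS": 0.33,
            "benign": 0.30,
            "aneuploid": 0.05,
        }
    )
    seed: int = 7

    def validate(self) -> None:
        total = sum(self.tier_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"tier mixture sums to {total}, expected 1")


@dataclass
class InterpFixtures:
    cnvs: list[CNVCall]
    kbs: KnowledgeBaseSet
    truth: pd.DataFrame  # planted tier per CNV
    cytobands: CytobandTable
    filters: AnnotationFilterConfig
    scoring: ScoringConfig
    rules: ClassificationRuleConfig


def simulate_interpretation_fixtures(config: InterpSimConfig | None = None) -> InterpFixtures:
    """Plant CNVs and co-designed KB evidence recovering known tiers."""
    config = config or InterpSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cytobands = toy_cytobands()
    kbs = KnowledgeBaseSet(version="synthetic")
    rules = ClassificationRuleConfig()
    scoring = ScoringConfig()
    blocklist: list[Region] = []

    tiers = list(config.tier_mixture)
    probs = np.array([config.tier_mixture[t] for t in tiers])
    probs = probs / probs.sum()
    autosomes = [str(i) for i in range(1, 23)]
    cursor = {c: 5_000_000 for c in autosomes}
    chrom_cycle = 0

    cnvs: list[CNVCall] = []
    rows = []
    for i in range(config.n_cnvs):
        tier = tiers[int(rng.choice(len(tiers), p=probs))]
        vtype = (
            VariationType.HETEROZYGOUS_DELETION
            if rng.random() < 0.5
            else VariationType.DUPLICATION
        )
        mechanism = "deletion" if vtype.is_loss else "duplication"

        if tier == "aneuploid":
            chrom = autosomes[chrom_cycle % 22]
            chrom_cycle += 1
            length = cytobands.chrom_length(chrom)
            cnv = CNVCall(chrom, 1, length, vtype)
            kbs.aneuploid.add(
                AneuploidRecord(
                    chrom=chrom,
                    event="gain" if vtype.is_gain else "loss",
                    description_corpus=(
                        f"{'trisomy' if vtype.is_gain else 'monosomy'} {chrom} "
                        "karyotype with whole chromosome imbalance"
                    ),
                )
            )
            cnvs.append(cnv)
            rows.append((i, chrom, 1, length, vtype.value, "pathogenic", True, "aneuploid"))
            continue

        # allocate a disjoint slot so planted evidence stays private
        size = int(rng.integers(20, 300)) * 10_000  # 200 kb .. 3 Mb
        for _ in range(44):
            chrom = autosomes[chrom_cycle % 22]
            chrom_cycle += 1
            if cursor[chrom] + size + 5_000_000 < cytobands.chrom_length(chrom):
                break
        start = cursor[chrom]
        cursor[chrom] += size + 3_000_000
        cnv = CNVCall(chrom, start, start + size - 1, vtype)
        region = Region(chrom, cnv.start, cnv.end)
        mech_note = "none"

        if tier == "pathogenic":
            mech_note = ("syndrome", "gene", "paper")[i % 3]
            if mech_note == "syndrome":
                kbs.syndrome.add(
                    SyndromeRecord(
                        region=region,
                        syndrome_name=f"SYN{i}",
                        dosage_mechanism=mechanism,
                        corpus=f"syndrome SYN{i} with recurrent dysmorphic features",
                        source="synthetic",
                    )
                )
            elif mech_note == "gene":
                third = max(size // 3, 1)
                for g in range(2):
                    sub = Region(chrom, start + g * third, start + g * third + third - 1)
                    kbs.gene.add(
                        GeneRecord(
                            gene_symbol=f"GENE{i}_{g}",
                            region=sub,
                            dosage_sensitivity=(
                                "haploinsufficient" if vtype.is_loss else "triplosensitive"
                            ),
                            corpus=f"gene GENE{i}_{g} dosage sensitive",
                            source="synthetic",
                        )
                    )
            else:
                kbs.paper.add(
                    PaperRecord(
                        region=region,
                        plp_case_count=int(rng.integers(10, 26)),
                        citation=f"PMID{i}",
                        corpus="literature reports many affected cases",
                    )
                )
        elif tier == "likely_pathogenic":
            mech_note = ("syndrome", "gene", "paper")[i % 3]
            if mech_note == "syndrome":
                # larger record: overlap_db = size/(size+2*pad) lands in
                # [0.55, 0.75), between the likely and pathogenic thresholds
                pad = int(size * rng.uniform(0.17, 0.40))
                big = Region(chrom, max(1, start - pad), start + size - 1 + pad)
                kbs.syndrome.add(
                    SyndromeRecord(
                        region=big,
                        syndrome_name=f"SYN{i}",
                        dosage_mechanism=mechanism,
                        corpus=f"syndrome SYN{i} partially overlapping region",
                        source="synthetic",
                    )
                )
            elif mech_note == "gene":
                kbs.gene.add(
                    GeneRecord(
                        gene_symbol=f"GENE{i}",
                        region=region,
                        dosage_sensitivity=(
                            "haploinsufficient" if vtype.is_loss else "triplosensitive"
                        ),
                        corpus=f"gene GENE{i} dosage sensitive",
                        source="synthetic",
                    )
                )
            else:
                kbs.paper.add(
                    PaperRecord(
                        region=region,
                        plp_case_count=int(rng.integers(3, 10)),
                        citation=f"PMID{i}",
                        corpus="literature reports a few cases",
                    )
                )
        elif tier == "benign":
            kbs.polymorphism.add(
                PolymorphismRecord(
                    region=region,
                    frequency=float(rng.uniform(0.02, 0.2)),
                    sample_size=int(rng.integers(2000, 20000)),
                    source="synthetic",
                )
            )
        else:  # VOUS: either no evidence or an inert decoy
            decoy = int(rng.integers(0, 5))
            if decoy == 1:  # underpowered study
                kbs.polymorphism.add(
                    PolymorphismRecord(region=region, frequency=0.05, sample_size=100)
                )
            elif decoy == 2:  # mechanism mismatch
                kbs.syndrome.add(
                    SyndromeRecord(
                        region=region,
                        syndrome_name=f"SYN{i}",
                        dosage_mechanism="duplication" if vtype.is_loss else "deletion",
                        corpus="syndrome with opposite dosage mechanism",
                    )
                )
            elif decoy == 3:  # too few published cases
                kbs.paper.add(
                    PaperRecord(region=region, plp_case_count=int(rng.integers(0, 3)))
                )
            elif decoy == 4:  # incomplete penetrance: evidence annotated only
                kbs.syndrome.add(
                    SyndromeRecord(
                        region=region,
                        syndrome_name=f"SYN{i}",
                        dosage_mechanism=mechanism,
                        corpus="recurrent incomplete penetrance region",
                    )
                )
                blocklist.append(region)
            mech_note = f"decoy{decoy}"
        # patient-store annotations never influence the call
        if rng.random() < 0.15:
            kbs.patient.add(
                PatientRecord(region=region, phenotype="patient with ultrasound findings")
            )

        cnvs.append(cnv)
        rows.append((i, chrom, cnv.start, cnv.end, vtype.value, tier, False, mech_note))

    truth = pd.DataFrame(
        rows,
        columns=[
            "cnv_index",
            "chrom",
            "start",
            "end",
            "variation_type",
            "planted_tier",
            "is_aneuploid",
            "mechanism",
        ],
    )
    filters = AnnotationFilterConfig(incomplete_penetrance_regions=tuple(blocklist))
    return InterpFixtures(
        cnvs=cnvs,
        kbs=kbs,
        truth=truth,
        cytobands=cytobands,
        filters=filters,
        scoring=scoring,
        rules=ClassificationRuleConfig(),
    )
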