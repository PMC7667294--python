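"""Core domain types for the CNV post-detection pipeline.

The pipeline mines historical clinical reports (one free-text explanation
paragraph per sample, possibly covering several variants) into a labeled
corpus, builds evidence knowledge bases, and classifies copy-number variants
on the ACMG five-tier scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


ALLOWED_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

#: Calling platforms report CNVs at or above this size; whole-chromosome
#: events and toy fixtures may be smaller, so this is enforced only at the
#: call-table ingestion boundary, not in the dataclass.
MIN_CNV_LENGTH_BP = 100_000


class VariationType(str, enum.Enum):
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    HETEROZYGOUS_DELETION = "heterozygous_deletion"
    DUPLICATION = "duplication"
    TRIPLICATION = "triplication"

    @property
    def is_loss(self) -> bool:
        return self in (self.HOMOZYGOUS_DELETION, self.HETEROZYGOUS_DELETION)

    @property
    def is_gain(self) -> bool:
        return not self.is_loss


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class SampleType(str, enum.Enum):
    PRENATAL = "prenatal"
    POC = "POC"


class Category(str, enum.Enum):
    """Sentence categories of the labeled corpus."""

    BASIC = "Basic"
    ANEUPLOID = "Aneuploid"
    SYNDROME = "Syndrome"
    GENE = "Gene"
    PAPER = "Paper"
    PATIENT = "Patient"


CATEGORIES: tuple[Category, ...] = tuple(Category)


class FiveTier(str, enum.Enum):
    """ACMG five-tier classification scale."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VOUS = "VOUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @property
    def is_pcnv(self) -> bool:
        """Pathogenic or likely pathogenic — the positive reporting class."""
        return self in (self.PATHOGENIC, self.LIKELY_PATHOGENIC)

    @property
    def reported(self) -> str:
        """Reporting collapses benign and likely benign into 'benign'."""
        if self is FiveTier.LIKELY_BENIGN:
            return FiveTier.BENIGN.value
        return self.value


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix and validate against the allowed set."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.lower() in ("x", "y") else c
    if c not in ALLOWED_CHROMS:
        raise ValueError(f"unknown chromosome {chrom!r}")
    return c


@dataclass(frozen=True)
class CNVCall:
    """A copy-number variant call. Coordinates are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    variation_type: VariationType
    gender: Gender = Gender.UNKNOWN
    sample_type: SampleType = SampleType.PRENATAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "variation_type", VariationType(self.variation_type))
        object.__setattr__(self, "gender", Gender(self.gender))
        object.__setattr__(self, "sample_type", SampleType(self.sample_type))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Sentence:
    text: str
    index: int
    begin_label: str | None = None  # "begin" | "not_begin"
    category: Category | None = None


@dataclass
class SubParagraph:
    """Contiguous run of sentences explaining one variant."""

    sentences: list[Sentence]
    source_report_id: str = ""
    matched_cnv_index: int | None = None

    @property
    def text(self) -> str:
        return ", ".join(s.text for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class RelationScore:
    """Binary keyword-match components relating a CNV to a sub-paragraph.

    The total is the weighted sum 5*chr + 2*type + cyto + length; the
    chromosome dominates because it is the least ambiguous keyword.
    """

    chr_score: int
    type_score: int
    cyto_score: int
    length_score: int

    def __post_init__(self) -> None:
        for name in ("chr_score", "type_score", "cyto_score", "length_score"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be binary, got {v}")

    @property
    def total(self) -> int:
        return (
            5 * self.chr_score
            + 2 * self.type_score
            + self.cyto_score
            + self.length_score
        )


@dataclass
class ClinicalReport:
    """A historical record: the reported variants plus one explanation paragraph."""

    report_id: str
    cnvs: list[CNVCall]
    paragraph: str
    sample_type: SampleType = SampleType.PRENATAL
    gender: Gender = Gender.UNKNOWN

    @property
    def is_single_cnv(self) -> bool:
        return len(self.cnvs) == 1


@dataclass
class LabeledSentenceRow:
    """One row of the labeled-corpus TSV interchange format."""

    report_id: str
    sub_index: int
    sent_index: int
    text: str
    begin_label: str
    category: str
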