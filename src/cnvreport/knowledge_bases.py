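"""The six clinical evidence knowledge bases.

Polymorphism, Aneuploid, Syndrome, Gene, Paper and Patient stores hold
*evidence only* — never a precomputed variant classification — so the
classification of a historical report can never leak into a new call.
(The Patient store's ``reported_classification`` is display-only: patient
records are used in annotation, never in scoring.)

Stores are interval-indexed per chromosome; regions are 1-based inclusive.
Corpus-derived records take the region of the sub-paragraph's matched CNV;
public-database-shaped tables are ingested directly.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

from .models import CNVCall, Category, FiveTier, SubParagraph, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PolymorphismRecord:
    region: Region
    frequency: float
    sample_size: int
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass(frozen=True)
class AneuploidRecord:
    chrom: str
    event: str  # gain | loss | mosaic | heteroploidy
    description_corpus: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.event not in ("gain", "loss", "mosaic", "heteroploidy"):
            raise ValueError(f"unknown aneuploid event {self.event!r}")


@dataclass(frozen=True)
class SyndromeRecord:
    region: Region
    syndrome_name: str
    dosage_mechanism: str  # deletion | duplication | both
    corpus: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.dosage_mechanism not in ("deletion", "duplication", "both"):
            raise ValueError(f"bad dosage_mechanism {self.dosage_mechanism!r}")


@dataclass(frozen=True)
class GeneRecord:
    gene_symbol: str
    region: Region
    dosage_sensitivity: str  # haploinsufficient | triplosensitive | both | none
    corpus: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("empty gene symbol")
        if self.dosage_sensitivity not in (
            "haploinsufficient",
            "triplosensitive",
            "both",
            "none",
        ):
            raise ValueError(f"bad dosage_sensitivity {self.dosage_sensitivity!r}")


@dataclass(frozen=True)
class PaperRecord:
    region: Region
    plp_case_count: int  # reported P/LP cases; one trio counts once
    citation: str = ""
    corpus: str = ""

    def __post_init__(self) -> None:
        if self.plp_case_count < 0:
            raise ValueError("plp_case_count must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    region: Region
    phenotype: str = ""
    reported_classification: FiveTier | None = None
    source: str = "open_access"  # open_access | in_house


STORE_NAMES = ("polymorphism", "aneuploid", "syndrome", "gene", "paper", "patient")
_RECORD_TYPES = {
    "polymorphism": PolymorphismRecord,
    "aneuploid": AneuploidRecord,
    "syndrome": SyndromeRecord,
    "gene": GeneRecord,
    "paper": PaperRecord,
    "patient": PatientRecord,
}


class RegionStore:
    """Interval-indexed record store (all stores except Aneuploid)."""

    def __init__(self, records: Iterable = ()):  # records carry a .region
        self._trees: dict[str, IntervalTree] = {}
        self.records: list = []
        for rec in records:
            self.add(rec)

    def add(self, record) -> None:
        r: Region = record.region
        tree = self._trees.setdefault(r.chrom, IntervalTree())
        # interval tree is half-open; store [start, end+1)
        tree.addi(r.start, r.end + 1, len(self.records))
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def query(self, chrom: str, start: int, end: int) -> list[tuple[object, int]]:
        """All records intersecting the 1-based inclusive interval.

        Returns (record, overlap_bp) sorted by decreasing overlap, ties by
        insertion order.
        """
        chrom = normalize_chrom(chrom)
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end + 1):
            rec = self.records[iv.data]
            overlap = min(end, rec.region.end) - max(start, rec.region.start) + 1
            if overlap > 0:
                hits.append((iv.data, rec, overlap))
        hits.sort(key=lambda h: (-h[2], h[0]))
        return [(rec, overlap) for _, rec, overlap in hits]


class AneuploidStore:
    """Whole-chromosome event records, keyed by chromosome."""

    def __init__(self, records: Iterable[AneuploidRecord] = ()):
        self.records: list[AneuploidRecord] = list(records)

    def add(self, record: AneuploidRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def query(self, chrom: str, event: str | None = None) -> list[AneuploidRecord]:
        chrom = normalize_chrom(chrom)
        return [
            r
            for r in self.records
            if r.chrom == chrom and (event is None or r.event in (event, "mosaic", "heteroploidy"))
        ]


@dataclass
class KnowledgeBaseSet:
    polymorphism: RegionStore = field(default_factory=RegionStore)
    aneuploid: AneuploidStore = field(default_factory=AneuploidStore)
    syndrome: RegionStore = field(default_factory=RegionStore)
    gene: RegionStore = field(default_factory=RegionStore)
    paper: RegionStore = field(default_factory=RegionStore)
    patient: RegionStore = field(default_factory=RegionStore)
    version: str = ""

    def store(self, name: str):
        if name not in STORE_NAMES:
            raise KeyError(f"unknown store {name!r}")
        return getattr(self, name)

    def sizes(self) -> dict[str, int]:
        return {name: len(self.store(name)) for name in STORE_NAMES}


def query_region(store: RegionStore, region: Region) -> list[tuple[object, int]]:
    """Records intersecting ``region`` with exact overlap length in bp."""
    return store.query(region.chrom, region.start, region.end)


# ---------------------------------------------------------------------------
# building from labeled corpus + public-DB-shaped tables

_CASE_COUNT_RE = re.compile(r"(\d+)\s+(?:p/lp\s+)?(?:case|patient)s?", re.IGNORECASE)


def _paper_case_count(text: str) -> int:
    m = _CASE_COUNT_RE.search(text)
    return int(m.group(1)) if m else 1


def build_knowledge_bases(
    labeled_subs: Iterable[SubParagraph],
    cnvs_by_report: dict[str, list[CNVCall]] | None = None,
    public_tables: dict[str, Iterable] | None = None,
    version: str | None = None,
) -> KnowledgeBaseSet:
    """Route labeled corpus sentences and public tables into the six stores.

    Corpus routing by sentence category: Syndrome/Gene/Paper/Aneuploid/
    Patient sentences become evidence records at the sub-paragraph's matched
    CNV region; Basic sentences describe the call itself and are not stored
    as evidence.  Duplicate regions within a store are merged with corpus
    concatenation (Paper: case counts summed over distinct citations).
    """
    kbs = KnowledgeBaseSet(version=version or _dt.date.today().isoformat())

    # public (already-shaped) records first, so merging sees them
    for name, records in (public_tables or {}).items():
        store = kbs.store(name)
        for rec in records:
            expected = _RECORD_TYPES[name]
            if not isinstance(rec, expected):
                raise TypeError(f"store {name!r} expects {expected.__name__}")
            store.add(rec)

    merged_syndrome: dict[Region, list[str]] = {}
    merged_gene: dict[Region, list[str]] = {}
    merged_paper: dict[Region, list[tuple[str, str]]] = {}

    for sub in labeled_subs:
        if sub.matched_cnv_index is None:
            logger.warning(
                "sub-paragraph from report %r has no matched CNV; skipped",
                sub.source_report_id,
            )
            continue
        if cnvs_by_report is None:
            raise ValueError("cnvs_by_report required to resolve matched CNVs")
        cnv = cnvs_by_report[sub.source_report_id][sub.matched_cnv_index]
        region = Region(cnv.chrom, cnv.start, cnv.end)
        by_cat: dict[Category, list[str]] = {}
        for s in sub.sentences:
            if s.category is None:
                raise ValueError("corpus sentence without category")
            by_cat.setdefault(Category(s.category), []).append(s.text)

        if Category.SYNDROME in by_cat:
            merged_syndrome.setdefault(region, []).extend(by_cat[Category.SYNDROME])
        if Category.GENE in by_cat:
            merged_gene.setdefault(region, []).extend(by_cat[Category.GENE])
        if Category.PAPER in by_cat:
            text = ", ".join(by_cat[Category.PAPER])
            merged_paper.setdefault(region, []).append((sub.source_report_id, text))
        if Category.ANEUPLOID in by_cat:
            kbs.aneuploid.add(
                AneuploidRecord(
                    chrom=cnv.chrom,
                    event="gain" if cnv.variation_type.is_gain else "loss",
                    description_corpus=", ".join(by_cat[Category.ANEUPLOID]),
                )
            )
        if Category.PATIENT in by_cat:
            kbs.patient.add(
                PatientRecord(
                    region=region,
                    phenotype=", ".join(by_cat[Category.PATIENT]),
                    source="in_house",
                )
            )
        # Basic sentences are descriptive only: not evidence.

    mechanism = {True: "deletion", False: "duplication"}
    for region, texts in merged_syndrome.items():
        kbs.syndrome.add(
            SyndromeRecord(
                region=region,
                syndrome_name="corpus-derived",
                dosage_mechanism="both",
                corpus=", ".join(texts),
                source="labeled_corpus",
            )
        )
    del mechanism
    for region, texts in merged_gene.items():
        kbs.gene.add(
            GeneRecord(
                gene_symbol="corpus-derived",
                region=region,
                dosage_sensitivity="both",
                corpus=", ".join(texts),
                source="labeled_corpus",
            )
        )
    for region, entries in merged_paper.items():
        distinct = {}
        for citation, text in entries:
            distinct.setdefault(citation, text)
        kbs.paper.add(
            PaperRecord(
                region=region,
                plp_case_count=sum(_paper_case_count(t) for t in distinct.values()),
                citation=";".join(sorted(distinct)),
                corpus=", ".join(distinct.values()),
            )
        )
    return kbs


# ---------------------------------------------------------------------------
# serialization: one TSV per store + a JSON manifest

_FORBIDDEN_EVIDENCE_FIELDS = {"classification", "five_tier", "tier", "acmg_class"}


def _record_to_row(rec) -> dict[str, str]:
    row: dict[str, str] = {}
    for f in dc_fields(rec):
        v = getattr(rec, f.name)
        if isinstance(v, Region):
            row["chrom"], row["start"], row["end"] = v.chrom, str(v.start), str(v.end)
        elif v is None:
            row[f.name] = ""
        elif isinstance(v, FiveTier):
            row[f.name] = v.value
        else:
            row[f.name] = str(v)
    return row


def _row_to_record(name: str, row: dict[str, str]):
    cls = _RECORD_TYPES[name]
    kwargs = {}
    for f in dc_fields(cls):
        if f.name == "region":
            kwargs["region"] = Region(row["chrom"], int(row["start"]), int(row["end"]))
        elif f.name in ("frequency",):
            kwargs[f.name] = float(row[f.name])
        elif f.name in ("sample_size", "plp_case_count"):
            kwargs[f.name] = int(row[f.name])
        elif f.name == "reported_classification":
            kwargs[f.name] = FiveTier(row[f.name]) if row.get(f.name) else None
        else:
            kwargs[f.name] = row.get(f.name, "")
    return cls(**kwargs)


def write_knowledge_bases(kbs: KnowledgeBaseSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in STORE_NAMES:
        store = kbs.store(name)
        rows = [_record_to_row(r) for r in store.records]
        header: list[str] = []
        for row in rows:
            for key in row:
                if key not in header:
                    header.append(key)
        if not header:
            header = ["chrom", "start", "end"]
        if name != "patient":
            bad = set(h.lower() for h in header) & _FORBIDDEN_EVIDENCE_FIELDS
            if bad:
                raise ValueError(
                    f"store {name!r} may not serialize classification fields: {sorted(bad)}"
                )
        with open(directory / f"{name}.tsv", "wt") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row.get(h, "") for h in header) + "\n")
    manifest = {"version": kbs.version, "stores": kbs.sizes()}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_knowledge_bases(directory: str | Path) -> KnowledgeBaseSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    kbs = KnowledgeBaseSet(version=manifest.get("version", ""))
    for name in STORE_NAMES:
        path = directory / f"{name}.tsv"
        if not path.exists():
            continue
        with open(path, "rt") as fh:
            lines = fh.read().splitlines()
        if not lines:
            continue
        header = lines[0].split("\t")
        if name != "patient":
            bad = set(h.lower() for h in header) & _FORBIDDEN_EVIDENCE_FIELDS
            if bad:
                raise ValueError(
                    f"store {name!r} carries classification fields {sorted(bad)}: "
                    "knowledge bases hold evidence only"
                )
        store = kbs.store(name)
        for line in lines[1:]:
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            store.add(_row_to_record(name, row))
    return kbs
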