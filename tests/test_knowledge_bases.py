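"""Knowledge-base stores: building, querying, serialization."""

import numpy as np
import pytest

from cnvreport.knowledge_bases import (
    AneuploidRecord,
    KnowledgeBaseSet,
    PaperRecord,
    PatientRecord,
    PolymorphismRecord,
    Region,
    RegionStore,
    SyndromeRecord,
    build_knowledge_bases,
    query_region,
    read_knowledge_bases,
    write_knowledge_bases,
)
from cnvreport.models import CNVCall, Category, Sentence, SubParagraph


def _poly(chrom, start, end, freq=0.05, n=5000):
    return PolymorphismRecord(Region(chrom, start, end), freq, n)


class TestQueryRegion:
    def test_overlap_arithmetic_one_based_inclusive(self):
        store = RegionStore([_poly("1", 150, 250)])
        (record, overlap), = store.query("1", 100, 200)
        assert overlap == 51

    def test_disjoint_query_returns_empty(self):
        store = RegionStore([_poly("1", 150, 250)])
        assert store.query("1", 300, 400) == []
        assert store.query("2", 150, 250) == []

    def test_sorted_by_decreasing_overlap(self):
        store = RegionStore([_poly("1", 100, 120), _poly("1", 100, 200)])
        hits = store.query("1", 100, 200)
        assert [h[1] for h in hits] == [101, 21]

    def test_matches_brute_force_on_random_store(self):
        rng = np.random.default_rng(11)
        records = []
        for _ in range(200):
            start = int(rng.integers(1, 10_000))
            records.append(_poly("1", start, start + int(rng.integers(1, 500))))
        store = RegionStore(records)
        for _ in range(50):
            qs = int(rng.integers(1, 10_000))
            qe = qs + int(rng.integers(1, 800))
            got = {(id(r), o) for r, o in store.query("1", qs, qe)}
            expected = set()
            for r in records:
                o = min(qe, r.region.end) - max(qs, r.region.start) + 1
                if o > 0:
                    expected.add((id(r), o))
            assert got == expected


def _labeled_sub(report_id, cnv_index, cat_texts):
    sents = [
        Sentence(text=t, index=i, category=c) for i, (c, t) in enumerate(cat_texts)
    ]
    return SubParagraph(sentences=sents, source_report_id=report_id, matched_cnv_index=cnv_index)


class TestBuild:
    def test_category_routing(self):
        cnvs = {"r1": [CNVCall("3", 1000, 5000, "duplication")]}
        sub = _labeled_sub(
            "r1",
            0,
            [
                (Category.BASIC, "a 4 Kb duplication"),
                (Category.SYNDROME, "syndrome description"),
                (Category.GENE, "gene dosage text"),
                (Category.PAPER, "literature reports 4 cases"),
                (Category.PATIENT, "patient phenotype"),
            ],
        )
        kbs = build_knowledge_bases([sub], cnvs_by_report=cnvs)
        assert kbs.sizes() == {
            "polymorphism": 0,
            "aneuploid": 0,
            "syndrome": 1,
            "gene": 1,
            "paper": 1,
            "patient": 1,
        }
        (syn, _), = query_region(kbs.syndrome, Region("3", 1000, 5000))
        assert syn.corpus == "syndrome description"
        (paper, _), = query_region(kbs.paper, Region("3", 1000, 5000))
        assert paper.plp_case_count == 4  # parsed from "4 cases"

    def test_basic_sentences_are_not_evidence(self):
        cnvs = {"r1": [CNVCall("3", 1000, 5000, "duplication")]}
        sub = _labeled_sub("r1", 0, [(Category.BASIC, "basic only")])
        kbs = build_knowledge_bases([sub], cnvs_by_report=cnvs)
        assert sum(kbs.sizes().values()) == 0

    def test_unmatched_sub_skipped_with_warning(self, caplog):
        sub = _labeled_sub("r1", None, [(Category.SYNDROME, "text")])
        with caplog.at_level("WARNING"):
            kbs = build_knowledge_bases([sub], cnvs_by_report={})
        assert sum(kbs.sizes().values()) == 0
        assert "no matched CNV" in caplog.text

    def test_duplicate_regions_merge(self):
        cnvs = {"r1": [CNVCall("3", 1000, 5000, "duplication")],
                "r2": [CNVCall("3", 1000, 5000, "duplication")]}
        subs = [
            _labeled_sub("r1", 0, [(Category.PAPER, "literature notes 2 cases")]),
            _labeled_sub("r2", 0, [(Category.PAPER, "literature notes 3 cases")]),
        ]
        kbs = build_knowledge_bases(subs, cnvs_by_report=cnvs)
        assert len(kbs.paper) == 1
        assert kbs.paper.records[0].plp_case_count == 5

    def test_aneuploid_routing(self):
        cnvs = {"r1": [CNVCall("21", 1, 200_000_000, "duplication")]}
        sub = _labeled_sub("r1", 0, [(Category.ANEUPLOID, "trisomy 21 karyotype")])
        kbs = build_knowledge_bases([sub], cnvs_by_report=cnvs)
        (rec,) = kbs.aneuploid.query("21", "gain")
        assert rec.description_corpus == "trisomy 21 karyotype"


class TestSerialization:
    def _sample_kbs(self):
        kbs = KnowledgeBaseSet(version="v-test")
        kbs.polymorphism.add(_poly("1", 100, 900, 0.12, 3000))
        kbs.syndrome.add(
            SyndromeRecord(Region("2", 10, 90), "ToySyn", "deletion", "syndrome text", "src")
        )
        kbs.paper.add(PaperRecord(Region("2", 10, 90), 7, "PMID1", "literature text"))
        kbs.aneuploid.add(AneuploidRecord("21", "gain", "trisomy 21"))
        kbs.patient.add(
            PatientRecord(Region("2", 10, 90), "phenotype", None, "open_access")
        )
        return kbs

    def test_round_trip_preserves_query_results(self, tmp_path):
        kbs = self._sample_kbs()
        write_knowledge_bases(kbs, tmp_path)
        again = read_knowledge_bases(tmp_path)
        assert again.version == "v-test"
        assert again.sizes() == kbs.sizes()
        for store_name in ("polymorphism", "syndrome", "paper", "patient"):
            q = Region("2", 1, 1000) if store_name != "polymorphism" else Region("1", 1, 1000)
            got = query_region(again.store(store_name), q)
            expected = query_region(kbs.store(store_name), q)
            assert got == expected  # frozen records compare by value
        assert again.aneuploid.query("21", "gain")[0].description_corpus == "trisomy 21"

    def test_evidence_stores_reject_classification_columns(self, tmp_path):
        kbs = self._sample_kbs()
        write_knowledge_bases(kbs, tmp_path)
        path = tmp_path / "syndrome.tsv"
        lines = path.read_text().splitlines()
        lines[0] += "\tclassification"
        lines[1] += "\tpathogenic"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="evidence only"):
            read_knowledge_bases(tmp_path)

    def test_patient_store_may_carry_display_classification(self, tmp_path):
        kbs = KnowledgeBaseSet()
        kbs.patient.add(
            PatientRecord(Region("1", 1, 10), "pheno", None, "open_access")
        )
        write_knowledge_bases(kbs, tmp_path)
        read_knowledge_bases(tmp_path)  # no error: display-only field
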