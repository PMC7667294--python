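"""Overlap fractions, annotation filters, evidence scores, classification."""

import dataclasses

import numpy as np
import pytest

from cnvreport.interpretation import (
    AnnotationFilterConfig,
    ClassificationRuleConfig,
    EvidenceScores,
    ScoringConfig,
    annotate_cnv,
    classify_variant,
    evidence_scores,
    interpret_cnv,
    overlap_fractions,
)
from cnvreport.knowledge_bases import (
    GeneRecord,
    KnowledgeBaseSet,
    PaperRecord,
    PatientRecord,
    PolymorphismRecord,
    Region,
    SyndromeRecord,
)
from cnvreport.models import CNVCall, FiveTier


def _cnv(chrom="1", start=101, end=200, vtype="heterozygous_deletion"):
    return CNVCall(chrom, start, end, vtype)


class TestOverlapFractions:
    def test_half_overlap(self):
        f = overlap_fractions(_cnv(), Region("1", 151, 250))
        assert (f.overlap_bp, f.overlap_db, f.overlap_query) == (50, 0.5, 0.5)

    def test_identical_intervals(self):
        f = overlap_fractions(_cnv(), Region("1", 101, 200))
        assert (f.overlap_bp, f.overlap_db, f.overlap_query) == (100, 1.0, 1.0)

    def test_nested_record_ten_percent_of_query(self):
        f = overlap_fractions(_cnv(start=1, end=1000), Region("1", 101, 200))
        assert f.overlap_db == 1.0
        assert f.overlap_query == pytest.approx(0.1)

    def test_different_chromosomes_give_zeros_not_error(self):
        f = overlap_fractions(_cnv(), Region("2", 101, 200))
        assert (f.overlap_bp, f.overlap_db, f.overlap_query) == (0, 0.0, 0.0)

    def test_fractions_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = sorted(rng.integers(1, 1000, size=2).tolist())
            c, d = sorted(rng.integers(1, 1000, size=2).tolist())
            f = overlap_fractions(_cnv(start=a, end=b + 1), Region("1", c, d + 1))
            assert 0.0 <= f.overlap_db <= 1.0
            assert 0.0 <= f.overlap_query <= 1.0


def _kbs_with(syndrome=(), gene=(), paper=(), poly=(), patient=()):
    kbs = KnowledgeBaseSet()
    for r in syndrome:
        kbs.syndrome.add(r)
    for r in gene:
        kbs.gene.add(r)
    for r in paper:
        kbs.paper.add(r)
    for r in poly:
        kbs.polymorphism.add(r)
    for r in patient:
        kbs.patient.add(r)
    return kbs


class TestAnnotationFilters:
    def test_exact_syndrome_hit_survives_default_thresholds(self):
        kbs = _kbs_with(syndrome=[SyndromeRecord(Region("1", 101, 200), "S", "deletion")])
        ann = annotate_cnv(_cnv(), kbs)
        assert len(ann.hits["syndrome"]) == 1

    def test_small_study_polymorphism_excluded(self):
        kbs = _kbs_with(poly=[PolymorphismRecord(Region("1", 101, 200), 0.1, 500)])
        ann = annotate_cnv(_cnv(), kbs)
        assert ann.hits["polymorphism"] == []

    def test_low_overlap_db_syndrome_excluded(self):
        kbs = _kbs_with(syndrome=[SyndromeRecord(Region("1", 1, 1000), "S", "deletion")])
        # overlap_db = 100/1000 = 0.1 < 0.5
        assert annotate_cnv(_cnv(), kbs).hits["syndrome"] == []

    def test_survivors_equal_brute_force_filtering(self):
        rng = np.random.default_rng(5)
        records = []
        for _ in range(50):
            s = int(rng.integers(1, 2000))
            records.append(
                SyndromeRecord(Region("1", s, s + int(rng.integers(10, 400))), "S", "deletion")
            )
        kbs = _kbs_with(syndrome=records)
        filters = AnnotationFilterConfig()
        for _ in range(25):
            qs = int(rng.integers(1, 2000))
            cnv = _cnv(start=qs, end=qs + int(rng.integers(10, 500)))
            got = {id(h.record) for h in annotate_cnv(cnv, kbs, filters).hits["syndrome"]}
            expected = set()
            for r in records:
                f = overlap_fractions(cnv, r.region)
                if f.overlap_bp > 0 and f.overlap_db >= 0.5:
                    expected.add(id(r))
            assert got == expected

    def test_incomplete_penetrance_hits_annotated_but_excluded(self):
        region = Region("1", 101, 200)
        kbs = _kbs_with(syndrome=[SyndromeRecord(region, "S", "deletion")])
        filters = AnnotationFilterConfig(incomplete_penetrance_regions=(region,))
        ann = annotate_cnv(_cnv(), kbs, filters)
        (hit,) = ann.hits["syndrome"]
        assert hit.excluded
        scores = evidence_scores(ann)
        assert scores.syndrome_score == 0.0
        assert classify_variant(scores) is FiveTier.VOUS


class TestEvidenceScores:
    def test_empty_annotation_scores_zero(self):
        ann = annotate_cnv(_cnv(), KnowledgeBaseSet())
        s = evidence_scores(ann)
        assert s == EvidenceScores()

    def test_paper_case_count_passes_through(self):
        kbs = _kbs_with(paper=[PaperRecord(Region("1", 101, 200), 7)])
        s = evidence_scores(annotate_cnv(_cnv(), kbs))
        assert s.paper_score == 7

    def test_duplication_over_haploinsufficient_gene_scores_zero(self):
        kbs = _kbs_with(
            gene=[GeneRecord("G", Region("1", 101, 200), "haploinsufficient")]
        )
        s = evidence_scores(annotate_cnv(_cnv(vtype="duplication"), kbs))
        assert s.gene_score == 0.0
        s2 = evidence_scores(annotate_cnv(_cnv(), kbs))  # deletion matches
        assert s2.gene_score == 1.0

    def test_benign_score_weights_frequency_by_query_coverage(self):
        kbs = _kbs_with(poly=[PolymorphismRecord(Region("1", 101, 150), 0.1, 5000)])
        s = evidence_scores(annotate_cnv(_cnv(), kbs))
        assert s.benign_score == pytest.approx(0.1 * 0.5)

    def test_monotone_in_case_count_and_frequency(self):
        base = _kbs_with(
            paper=[PaperRecord(Region("1", 101, 200), 4)],
            poly=[PolymorphismRecord(Region("1", 101, 200), 0.05, 5000)],
        )
        more = _kbs_with(
            paper=[PaperRecord(Region("1", 101, 200), 9)],
            poly=[PolymorphismRecord(Region("1", 101, 200), 0.2, 5000)],
        )
        s0 = evidence_scores(annotate_cnv(_cnv(), base))
        s1 = evidence_scores(annotate_cnv(_cnv(), more))
        assert s1.paper_score >= s0.paper_score
        assert s1.benign_score >= s0.benign_score

    def test_patient_hits_are_display_only(self):
        kbs = _kbs_with(patient=[PatientRecord(Region("1", 101, 200), "pheno")])
        s = evidence_scores(annotate_cnv(_cnv(), kbs))
        assert s.patient_annotations
        # no score field exists for patient evidence at all
        score_fields = {f.name for f in dataclasses.fields(EvidenceScores)}
        assert "patient_score" not in score_fields
        assert classify_variant(s) is FiveTier.VOUS


class TestClassification:
    def test_aneuploid_flag_always_pathogenic(self):
        s = EvidenceScores(benign_score=0.5, aneuploid_flag=True)
        assert classify_variant(s) is FiveTier.PATHOGENIC

    def test_all_zero_scores_are_vous(self):
        assert classify_variant(EvidenceScores()) is FiveTier.VOUS

    def test_high_benign_score_without_pathogenic_evidence(self):
        assert classify_variant(EvidenceScores(benign_score=0.12)) is FiveTier.BENIGN

    def test_ladder_thresholds(self):
        rules = ClassificationRuleConfig()
        assert classify_variant(EvidenceScores(syndrome_score=0.9), rules) is FiveTier.PATHOGENIC
        assert classify_variant(EvidenceScores(syndrome_score=0.6), rules) is FiveTier.LIKELY_PATHOGENIC
        assert classify_variant(EvidenceScores(gene_score=2), rules) is FiveTier.PATHOGENIC
        assert classify_variant(EvidenceScores(gene_score=1), rules) is FiveTier.LIKELY_PATHOGENIC
        assert classify_variant(EvidenceScores(paper_score=10), rules) is FiveTier.PATHOGENIC
        assert classify_variant(EvidenceScores(paper_score=3), rules) is FiveTier.LIKELY_PATHOGENIC

    def test_pathogenic_evidence_outranks_benign_score(self):
        s = EvidenceScores(syndrome_score=0.9, benign_score=0.5)
        assert classify_variant(s) is FiveTier.PATHOGENIC

    def test_determinism_across_runs(self, interp_fixtures):
        fx = interp_fixtures
        tiers1 = [
            interpret_cnv(c, fx.kbs, fx.filters, fx.scoring, fx.rules, fx.cytobands)[2]
            for c in fx.cnvs[:40]
        ]
        tiers2 = [
            interpret_cnv(c, fx.kbs, fx.filters, fx.scoring, fx.rules, fx.cytobands)[2]
            for c in fx.cnvs[:40]
        ]
        assert tiers1 == tiers2

    def test_hemizygous_x_male_flagged(self):
        cnv = CNVCall("X", 1_000_001, 2_000_000, "heterozygous_deletion", gender="male")
        ann = annotate_cnv(cnv, KnowledgeBaseSet())
        assert ann.hemizygous
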