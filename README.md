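# cnvreport

A post-detection pipeline for clinical copy-number-variant (CNV) reporting
in prenatal and products-of-conception (POC) diagnostics.

CNV *calling* is largely a solved engineering problem; the bottleneck in a
busy genetics laboratory is what happens afterwards: interpreting each
variant on the ACMG five-tier scale (benign / likely benign / VOUS /
likely pathogenic / pathogenic) and writing the diagnostic report. This
package automates that post-detection stage and, crucially, bootstraps its
evidence stores from the laboratory's own historical reports using natural
language processing — so the system encodes the local reporting practice
rather than a generic rulebook.

## What it does

**1. Corpus mining** (`cnvreport.text`, `segmentation`, `matching`,
`labeling`, `sequence_models`). Historical reports carry one free-text
explanation paragraph that may cover several variants. A three-step NLP
approach converts them into a labeled corpus:

* *Paragraph segmentation* — sentences (split on comma/period-class
  punctuation) are classified "begin"/"not begin" with TF-IDF + naive
  Bayes; sub-paragraphs are cut at begin sentences. Training labels come
  for free: the first sentence of every report is a positive, the rest of
  single-variant reports are negatives.
* *CNV–paragraph matching* — each variant C and sub-paragraph S get a
  relation score

      score(C, S) = 5·chr_score + 2·type_score + cyto_score + length_score

  where each component is 1 iff the variant's rendered keyword
  (chromosome token, "deletion"/"duplication", cytoband such as `p11.32`,
  formatted length such as `50 Mb`) occurs in the sub-paragraph; each
  variant takes the argmax sub-paragraph, first index on ties.
* *Corpus classification* — every sentence is assigned one of six
  categories (Basic, Aneuploid, Syndrome, Gene, Paper, Patient). Weak
  "programming" labels from keyword rules bootstrap a classifier
  (biLSTM+CRF over sentence vectors, implemented in numpy, plus a naive
  Bayes + CRF-transition baseline); sub-paragraphs with implausible label
  patterns (3 distinct categories in 3 consecutive sentences, or more than
  3 categories overall) are routed to an expert — pool-based active
  learning.

**2. Knowledge bases** (`cnvreport.knowledge_bases`). Six interval-indexed
evidence stores — Polymorphism, Aneuploid, Syndrome, Gene, Paper, Patient —
built from the labeled corpus plus public-database-shaped tables
(DGV/OMIM/DECIPHER/ClinGen/ClinVar extracts). The stores hold *evidence
only*, never a precomputed classification, so historical calls cannot leak
into new ones.

**3. Interpretation** (`cnvreport.interpretation`). Each call is annotated
with every overlapping record and its reciprocal overlap fractions
(`overlap_db` = overlap / record length, `overlap_query` = overlap / call
length), filtered by configurable thresholds, reduced to evidence scores
(polymorphism frequency × coverage, syndrome overlap with matched dosage
mechanism, dosage-sensitive gene count, published P/LP case count), and
classified by a deterministic rule ladder. Whole-chromosome events
(aneuploidy, mosaicism) are always pathogenic. Incomplete-penetrance
regions are annotated but never scored.

**4. Reporting** (`cnvreport.reporting`). One block per variant: a basic
description (cytoband, type, length — always containing the four matching
keywords), plus a special explanation assembled from knowledge-base corpus
text for pathogenic calls, the Aneuploid store description for
whole-chromosome events, or a fixed database-citation template for
benign/VOUS calls. Benign blocks are generated but flagged suppressed,
matching reporting practice.

**5. Evaluation & synthetic fixtures** (`cnvreport.evaluation`,
`simulate`). Binary diagnostic statistics (accuracy, PPV, NPV,
sensitivity, specificity, FPR, FNR, Cohen's kappa) from confusion counts,
per-class precision/recall/F1 — and seeded generators producing report
corpora and co-designed CNV/knowledge-base benchmarks with full ground
truth, so every stage is testable without proprietary clinical data.

## Worked example

```python
from cnvreport import (
    CNVCall, KnowledgeBaseSet, Region, interpret_cnv, compose_report, toy_cytobands,
)
from cnvreport.knowledge_bases import SyndromeRecord, PolymorphismRecord

cytobands = toy_cytobands()
kbs = KnowledgeBaseSet()
kbs.syndrome.add(SyndromeRecord(
    region=Region("7", 5_000_001, 6_500_000),
    syndrome_name="ToySyndrome",
    dosage_mechanism="deletion",
    corpus="syndrome ToySyndrome with recurrent craniofacial features",
))
kbs.polymorphism.add(PolymorphismRecord(
    region=Region("12", 40_000_001, 42_000_000), frequency=0.08, sample_size=8000,
))

calls = [
    CNVCall("7", 5_000_001, 6_500_000, "heterozygous_deletion"),
    CNVCall("12", 40_000_001, 42_000_000, "duplication"),
    CNVCall("2", 10_000_001, 11_000_000, "duplication"),
]
annotations, tiers = [], []
for cnv in calls:
    ann, scores, tier = interpret_cnv(cnv, kbs, cytobands=cytobands)
    annotations.append(ann); tiers.append(tier)
    print(f"{cnv.chrom}:{cnv.start}-{cnv.end} {cnv.variation_type.value:22s}"
          f" syndrome={scores.syndrome_score:.2f} benign={scores.benign_score:.3f}"
          f" -> {tier.value}")

report = compose_report("FAM-001", calls, tiers, kbs, cytobands,
                        annotations=annotations, suppress_benign=False)
print(report.to_text())
```

prints

```
7:5000001-6500000 heterozygous_deletion  syndrome=1.00 benign=0.000 -> pathogenic
12:40000001-42000000 duplication            syndrome=0.00 benign=0.080 -> benign
2:10000001-11000000 duplication            syndrome=0.00 benign=0.000 -> VOUS

Sample FAM-001 (prenatal) — pending_review
[pathogenic] a 1.5 Mb deletion on chromosome 7 at cytoband p15 (7p15), syndrome ToySyndrome with recurrent craniofacial features, this CNV is classified as pathogenic
[benign] a 2 Mb duplication on chromosome 12 at cytoband p12 (12p12), according to DGV, DECIPHER, OMIM, UCSC and PubMed databases and ACMG guidelines, this is a benign CNV
[VOUS] a 1 Mb duplication on chromosome 2 at cytoband p15 (2p15), according to DGV, DECIPHER, OMIM, UCSC and PubMed databases and ACMG guidelines, this is a VOUS CNV
```

The first call fully overlaps a deletion-sensitive syndrome region
(syndrome score 1.0 = the overlap fraction of the matched record), so it is
pathogenic and its explanation cites the knowledge-base corpus. The second
is covered by a common polymorphism (8% population frequency, study n =
8000), so it is benign and rendered — here unsuppressed — with the fixed
template sentence. The third has no evidence either way: VOUS.

A command-line surface mirrors the library
(`cnvreport corpus|kb|interpret|report|evaluate|simulate ...`); see
`cnvreport --help`.

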