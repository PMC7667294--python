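# Methods

This note documents the models and procedures implemented in `cnvreport`,
the parameters that matter, the synthetic benchmarks, and the design
choices made where the design was genuinely open. No number stated here is
asserted beyond what the test suite and `scripts/acceptance.py` compute at
run time.

## 1. Corpus mining

### Sentence splitting and tokenization

Explanation paragraphs are split on comma/period-class punctuation, with
ASCII (`, . ;`) and CJK (`， 。 ；`) delimiters both enabled by default
(the clinical corpora this design targets are Chinese; the synthetic
fixtures are English). A period flanked by digits on both sides is treated
as a decimal point, not a boundary, so length strings such as "1.26 Mb"
survive splitting intact. The tokenizer is pluggable; the default
lowercases, extracts word/number runs, and emits CJK text one character at
a time — the standard fallback when no dedicated CJK segmenter is
available. Both choices matter only through the models trained on top;
neither embeds language-specific rules elsewhere.

### Begin classification and segmentation

The "begin"/"not begin" sentence classifier is a scikit-learn pipeline:
TF-IDF (library defaults: L2 norm, no sublinear scaling, fitted on the
constructed training set only) into multinomial naive Bayes. Training data
follow the weak-supervision rule: the first sentence of every report is a
positive; the non-first sentences of single-variant reports are negatives
(in such reports no later sentence can open a new explanation). An input
with no single-variant reports is an error, since the negative class would
be empty. At segmentation time the first sentence of a paragraph is always
forced to "begin", which guarantees the partition property: concatenating
a report's sub-paragraphs restores its sentence sequence exactly.

### Relation scoring and matching

The relation score between a CNV and a sub-paragraph is the weighted sum
of four binary keyword matches — 5·chromosome + 2·type + cytoband +
length, maximum 9. The chromosome weight dominates because it is the least
ambiguous token; type words ("deletion"/"duplication") recur across
variants, hence the intermediate weight. Keyword rendering rules:

* *chromosome* — matched by configurable regular expressions covering
  `chr7`, `chromosome 7` and the CJK `7号` pattern, with a guard so `chr1`
  does not match `chr11`;
* *type* — `deletion` for homo/heterozygous deletions, `duplication`,
  `triplication`;
* *cytoband* — annotated from a UCSC-dialect cytoband table (0-based
  half-open; calls are 1-based inclusive and converted at the boundary);
  a multi-band CNV renders ISCN-style as firstBand+lastBand ("p11.32p11.31");
* *length* — ≥ 1 Mb as megabases with at most two decimals and trailing
  zeros trimmed ("50 Mb", "1.26 Mb"), otherwise integer kilobases
  ("480 Kb"); matching is case-insensitive.

Each CNV independently takes the argmax sub-paragraph, ties to the lowest
index; the assignment is deliberately many-to-one. The implementation is
tested against a brute-force argmax-with-first-tie oracle, exhaustively on
small matrices over all attainable totals and on random matrices up to 6×6.

### Programming labels and active learning

Weak labels come from an ordered keyword table (first matching rule wins;
sentences matching nothing fall back to Basic), e.g. "literature" → Paper.
Two triggers flag sub-paragraphs for expert review: (a) some window of
three consecutive sentences carries three distinct predicted categories,
or (b) the sub-paragraph contains more than three distinct categories. The
source description's "and" between the two conditions is ambiguous; the
default combines them with OR (more inclusive, more labels) and reports
each trigger separately; AND is available via an argument. Clinically,
explanations keep a topic over consecutive sentences, so both patterns
signal implausible label sequences worth an expert's minute.

### Sentence classification

Sentences are embedded as the mean of token vectors (out-of-vocabulary
tokens map deterministically to the zero vector; an empty sentence yields
the zero vector with a logged warning). The embedding table is a pluggable
text-format input; two in-package sources cover operation without
pretrained vectors: deterministic hashed random embeddings (a stable
random projection of the bag of words — the default for the benchmarks)
and a PPMI + truncated-SVD trainer for tiny corpora. Pretraining
large-corpus embeddings is out of scope.

Two contract-identical sequence classifiers consume a sub-paragraph as a
sequence of sentence vectors and emit one of the six categories per
sentence:

* **biLSTM+CRF** — a bidirectional LSTM (hidden size `num_units`) over the
  sentence vectors, a linear projection to per-class emissions, and a
  linear-chain CRF output layer trained end-to-end by exact negative
  log-likelihood (forward–backward gradients, checked against finite
  differences in the tests). Implemented directly in numpy: sub-paragraphs
  are short sequences, so CPU training is fast and the implementation
  stays dependency-free. Defaults: batch 64, 50 epochs, dropout 0.1 on the
  input vectors, learning rate 0.001 with Adam, maximum sequence length
  100 (longer inputs are classified in consecutive chunks), 200 hidden
  units, 200-dimensional embeddings. Training is deterministic given the
  config seed.
* **NB+CRF baseline** — Gaussian naive-Bayes per-sentence emissions with a
  Laplace-smoothed bigram transition matrix, decoded with Viterbi; with
  transitions disabled it degrades to the plain per-sentence classifier.
  This keeps the pipeline fully functional and testable on the same
  contract without the neural path.

## 2. Knowledge bases

Six stores: Polymorphism (region, allele frequency, study sample size),
Aneuploid (whole-chromosome gain/loss/mosaic/heteroploidy with a
description corpus), Syndrome (region, dosage mechanism, corpus), Gene
(symbol, region, haploinsufficiency/triplosensitivity, corpus), Paper
(region, published P/LP case count — one trio counts once — citation,
corpus), Patient (region, phenotype; display-only). Stores contain
evidence only; the serializers refuse classification-bearing columns in
the five evidence stores, so a variant classification can never be smuggled
in as evidence. The Patient store's `reported_classification` field is
permitted but is structurally unreachable from scoring.

Corpus routing: Syndrome/Gene/Paper/Aneuploid/Patient sentences of a
sub-paragraph become records at the region of the sub-paragraph's matched
CNV; Basic sentences describe the call itself and are not stored.
Duplicate regions merge with corpus concatenation; Paper records sum case
counts over distinct citations, parsing "N cases" from the text with a
fallback of one case per citation. Sub-paragraphs without a matched CNV
are skipped with a warning. Interval indexing uses an interval tree whose
results are tested equal to a brute-force scan.

## 3. Interpretation

For a call Q and record R on the same chromosome, with overlap o in bp:
`overlap_db = o / len(R)`, `overlap_query = o / len(Q)`; different
chromosomes yield zeros, not errors. The retrieval filters and every
numeric rule downstream are named config defaults — the semantics
(reciprocal overlaps, frequency, sample size, case counts, dosage
mechanisms) are fixed, the constants are not claimed to be canonical:

| parameter | default | role |
|---|---|---|
| min `overlap_db` (Syndrome, Gene) | 0.5 | record must be half-covered to count |
| min `overlap_query` (Paper) | 0.5 | case reports must concern most of the call |
| polymorphism min sample size | 1000 | ignore underpowered studies |
| benign frequency threshold | 0.01 | common-variant cutoff on frequency × `overlap_query` |
| gene min `overlap_db` per point | 0.5 | one point per dosage-matched sensitive gene |
| paper thresholds | 3 / 10 cases | likely-pathogenic / pathogenic |
| syndrome thresholds | 0.5 / 0.8 overlap_db | likely-pathogenic / pathogenic |
| whole-chromosome fraction | 0.99 | aneuploidy-scale span |

Evidence scores are monotone reductions (max or sum), so enlarging an
overlap, frequency, study size or case count never lowers a score. The
classification ladder, top to bottom: whole-chromosome event → pathogenic;
strong syndrome/gene/paper evidence → pathogenic; moderate → likely
pathogenic; common polymorphism and no pathogenic evidence → benign;
otherwise VOUS. Likely benign exists in the type system but the default
ladder reports benign for both, matching reporting practice. Dosage
mechanisms must match the call's direction (a duplication over a
haploinsufficient-only gene scores nothing). Hits whose record lies inside
a configured incomplete-penetrance region are annotated for review but
excluded from every score. A heterozygous deletion on X in a male is
flagged hemizygous in the annotation so reviewers see the semantics; the
flag does not enter the default ladder. The 2019 quantitative ACMG/ClinGen
point system and structural-rearrangement reasoning are out of scope.

## 4. Reporting

Every block renders the basic description so that it contains exactly the
four matcher keywords; the test suite asserts `relation_score = 9` for
every generated block against its own call — a cross-module consistency
check tying reporting back to matching. Pathogenic explanations
concatenate syndrome → gene → paper corpus text, then a significance
statement; whole-chromosome events use the Aneuploid store description
verbatim; benign/VOUS calls use a fixed template sentence citing the
public databases, with the class substituted. A pathogenic call with no
citable corpus raises: that is an interpretation/reporting inconsistency,
not a renderable state. Template strings live in a locale table (the
Chinese entry is a translation of the English sentence). Composition is
pure — identical inputs yield byte-identical output.

## 5. Evaluation

Binary metrics take pCNV (pathogenic or likely pathogenic) as the positive
class and are computed directly from confusion counts; Cohen's kappa uses
the marginal chance-agreement formula and is cross-checked against
scikit-learn on expanded label vectors. Ratios with zero denominators are
reported as undefined (None), never as 0. Display rounding is half-up to
one decimal percent; raw values are retained. Per-class tables are
one-vs-rest precision/recall/F1 with an unweighted macro average; classes
absent from both predictions and gold are excluded from the macro with a
warning.

## 6. Synthetic benchmarks

The generators are pure functions of (config, seed) and store complete
ground truth, so every stage can be scored without re-deriving labels.

**Corpus generator** (default 500 reports): 19% of reports carry 2–3
variants (mirroring the multi-variant share of the motivating corpus);
each variant gets one sub-paragraph whose begin sentence embeds the four
matching keywords, each independently dropped with probability 0.15; body
sentences draw a category from a fixed mixture and carry a trigger keyword
(same dropout), category-specific auxiliary vocabulary, and filler; with
probability 0.08 a distractor trigger from another category is inserted
(weak-label noise of the "linguistic diversity" kind); 15% of body
sentences are topic continuations — they inherit the previous sentence's
category with mostly generic wording, the property that makes sentence
*context* informative and a sequence model meaningful. 12% of variants are
whole-chromosome events with Aneuploid-flavored sub-paragraphs. The toy
genome is deterministic: 24 chromosomes with named p/q bands.

What the fixtures do **not** model: real clinical phrasing and its
long-tail variation, genuine Chinese text (the CJK code path is exercised
only at the unit level), inter-sentence syntax, label noise from human
annotators. Passing benchmarks therefore demonstrate that the machinery is
correct and well-calibrated on data with the *structural* properties of
the problem — not that the trained toy models transfer to real reports.

**Interpretation fixture** (default 200 CNVs, seed 7): calls are placed in
disjoint genomic slots so planted evidence stays private to its call;
tiers are planted by construction (pathogenic via matched syndrome /
two dosage-matched genes / ≥10 published cases, rotating; likely
pathogenic via partial-overlap syndrome, one gene, or 3–9 cases; benign
via a covering common polymorphism; VOUS via no evidence or an inert decoy
— an underpowered study, a mechanism-mismatched syndrome, too few cases,
or penetrance-blocklisted evidence). Aneuploidies span whole chromosomes
and carry an Aneuploid store description. Because evidence is co-designed
with the default thresholds, the ladder recovers the planted tiers
essentially exactly; the benchmark therefore validates plumbing,
filtering, exclusion and determinism rather than threshold calibration
against clinical truth.

## 7. Numerical and degenerate-input choices

* CRF computations in log space with `logsumexp`; Viterbi ties resolve to
  the lowest class index.
* LSTM forget-gate bias initialized to 1; Glorot-uniform weights from the
  config-seeded generator; gradients of the CRF layer are exact, not
  sampled.
* Empty paragraph → empty sentence list; empty sub-paragraph list into the
  matcher → error (there is nothing to assign).
* Calls below the 100 kb platform minimum are rejected at the call-table
  ingestion boundary only — in-memory construction stays unrestricted so
  toy genomes and unit fixtures remain expressible.
* Cytoband tables must be contiguous and non-overlapping per chromosome;
  violations raise with the offending bands named.

## 8. Known limitations

* The numeric thresholds of the interpretation layer are defensible
  defaults, not clinically validated constants; any deployment must
  calibrate them against expert-reviewed calls (the config surface exists
  for exactly that).
* The biLSTM+CRF is a faithful small-scale implementation; at a few
  hundred training sub-paragraphs its advantage over the naive-Bayes
  baselines is seed-dependent, and the benchmarks accordingly assert only
  that the transition-smoothed sequence model is at least as accurate as
  the per-sentence classifier.
* Matching assumes the explanation actually verbalizes the variant's
  coordinates/size/type; reports written in a style that omits them would
  need additional keyword renderers.
* One call is interpreted at a time; compound events (e.g. unbalanced
  translocations producing reciprocal CNVs) are not reasoned about
  jointly.
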