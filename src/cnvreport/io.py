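"""File interchange formats.

* Reports: JSON-lines, one report per line with the reported CNV fields and
  the free-text explanation paragraph.
* Labeled corpus: TSV with one sentence per row
  (report_id, sub_index, sent_index, text, begin_label, category).
* CNV call tables: TSV (chrom, start, end, variation_type[, gender,
  sample_type]), 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, TextIO

from .models import (
    MIN_CNV_LENGTH_BP,
    Category,
    ClinicalReport,
    CNVCall,
    Gender,
    LabeledSentenceRow,
    SampleType,
    Sentence,
    SubParagraph,
)


def read_reports_jsonl(source: str | Path | TextIO) -> list[ClinicalReport]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_reports_jsonl(fh)
    reports = []
    for line in source:
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        cnvs = [
            CNVCall(
                chrom=c["chrom"],
                start=int(c["start"]),
                end=int(c["end"]),
                variation_type=c["variation_type"],
                gender=c.get("gender", obj.get("gender", "unknown")),
                sample_type=obj.get("sample_type", "prenatal"),
            )
            for c in obj["cnvs"]
        ]
        reports.append(
            ClinicalReport(
                report_id=str(obj["report_id"]),
                cnvs=cnvs,
                paragraph=obj["paragraph"],
                sample_type=SampleType(obj.get("sample_type", "prenatal")),
                gender=Gender(obj.get("gender", "unknown")),
            )
        )
    return reports


def write_reports_jsonl(reports: Iterable[ClinicalReport], dest: str | Path | TextIO) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            write_reports_jsonl(reports, fh)
        return
    for r in reports:
        obj = {
            "report_id": r.report_id,
            "sample_type": r.sample_type.value,
            "gender": r.gender.value,
            "cnvs": [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "variation_type": c.variation_type.value,
                }
                for c in r.cnvs
            ],
            "paragraph": r.paragraph,
        }
        dest.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_labeled_corpus(
    subs_by_report: dict[str, list[SubParagraph]], dest: str | Path | TextIO
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            write_labeled_corpus(subs_by_report, fh)
        return
    writer = csv.writer(dest, delimiter="\t", lineterminator="\n")
    writer.writerow(["report_id", "sub_index", "sent_index", "text", "begin_label", "category"])
    for report_id, subs in subs_by_report.items():
        for sub_index, sub in enumerate(subs):
            for s in sub.sentences:
                writer.writerow(
                    [
                        report_id,
                        sub_index,
                        s.index,
                        s.text,
                        s.begin_label or "",
                        Category(s.category).value if s.category else "",
                    ]
                )


def read_labeled_corpus(source: str | Path | TextIO) -> dict[str, list[SubParagraph]]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_labeled_corpus(fh)
    reader = csv.reader(source, delimiter="\t")
    header = next(reader)
    rows = [LabeledSentenceRow(r[0], int(r[1]), int(r[2]), r[3], r[4], r[5]) for r in reader if r]
    del header
    out: dict[str, list[SubParagraph]] = {}
    for row in rows:
        subs = out.setdefault(row.report_id, [])
        while len(subs) <= row.sub_index:
            subs.append(SubParagraph(sentences=[], source_report_id=row.report_id))
        subs[row.sub_index].sentences.append(
            Sentence(
                text=row.text,
                index=row.sent_index,
                begin_label=row.begin_label or None,
                category=Category(row.category) if row.category else None,
            )
        )
    return out


def read_calls_tsv(
    source: str | Path | TextIO, enforce_min_length: bool = True
) -> list[CNVCall]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_calls_tsv(fh, enforce_min_length)
    reader = csv.DictReader(source, delimiter="\t")
    calls = []
    for row in reader:
        call = CNVCall(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            variation_type=row["variation_type"],
            gender=row.get("gender") or "unknown",
            sample_type=row.get("sample_type") or "prenatal",
        )
        if enforce_min_length and call.length_bp < MIN_CNV_LENGTH_BP:
            raise ValueError(
                f"call {call.chrom}:{call.start}-{call.end} is below the "
                f"{MIN_CNV_LENGTH_BP} bp platform minimum"
            )
        calls.append(call)
    return calls
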