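"""UCSC-style cytogenetic band tables and cytoband annotation.

The cytoBand file dialect is 0-based half-open, five tab-separated columns
(chrom, chromStart, chromEnd, name, gieStain).  CNV calls are 1-based
inclusive, the clinical convention; the conversion happens here at the
query boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from .models import CNVCall, VariationType, normalize_chrom


@dataclass(frozen=True)
class CytobandRecord:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    name: str
    stain: str = "gneg"


class CytobandTable:
    """Per-chromosome ordered, contiguous band records."""

    def __init__(self, records: Iterable[CytobandRecord]):
        self._by_chrom: dict[str, list[CytobandRecord]] = {}
        for rec in records:
            self._by_chrom.setdefault(rec.chrom, []).append(rec)
        for chrom, recs in self._by_chrom.items():
            recs.sort(key=lambda r: r.start)
            self._validate(chrom, recs)

    @staticmethod
    def _validate(chrom: str, recs: list[CytobandRecord]) -> None:
        prev = None
        for rec in recs:
            if rec.end <= rec.start:
                raise ValueError(f"empty band {rec.name} on chr{chrom}")
            if prev is not None:
                if rec.start < prev.end:
                    raise ValueError(
                        f"overlapping bands on chr{chrom}: "
                        f"{prev.name} [{prev.start},{prev.end}) and "
                        f"{rec.name} [{rec.start},{rec.end})"
                    )
                if rec.start > prev.end:
                    raise ValueError(
                        f"gap on chr{chrom} between {prev.name} (ends {prev.end}) "
                        f"and {rec.name} (starts {rec.start})"
                    )
            prev = rec

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def bands(self, chrom: str) -> list[CytobandRecord]:
        c = normalize_chrom(chrom)
        if c not in self._by_chrom:
            raise KeyError(f"chromosome {chrom!r} absent from cytoband table")
        return self._by_chrom[c]

    def chrom_length(self, chrom: str) -> int:
        return self.bands(chrom)[-1].end

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[CytobandRecord]:
        """Bands intersecting the 0-based half-open interval [start0, end0)."""
        return [b for b in self.bands(chrom) if b.start < end0 and b.end > start0]


def read_cytoband_table(source: str | Path | TextIO) -> CytobandTable:
    """Parse a UCSC cytoBand file (plain text, tab-separated)."""
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_cytoband_table(fh)
    records = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: expected >=4 tab-separated fields")
        chrom, start, end, name = fields[:4]
        stain = fields[4] if len(fields) > 4 else "gneg"
        records.append(
            CytobandRecord(normalize_chrom(chrom), int(start), int(end), name, stain)
        )
    return CytobandTable(records)


def write_cytoband_table(table: CytobandTable, dest: str | Path | TextIO) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            write_cytoband_table(table, fh)
        return
    for chrom in table.chroms:
        for b in table.bands(chrom):
            dest.write(f"chr{chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}\n")


def cytoband_label(cnv: CNVCall, cytobands: CytobandTable) -> str:
    """ISCN-style band label for a CNV.

    A CNV inside one band returns that band's name (e.g. ``"p11.32"``); a CNV
    spanning several bands returns the first and last band concatenated
    (e.g. ``"p11.32p11.31"``).
    """
    hits = cytobands.overlapping(cnv.chrom, cnv.start - 1, cnv.end)
    if not hits:
        raise ValueError(
            f"CNV {cnv.chrom}:{cnv.start}-{cnv.end} outside cytoband table range"
        )
    if len(hits) == 1:
        return hits[0].name
    return hits[0].name + hits[-1].name


def is_whole_chromosome_event(
    cnv: CNVCall, cytobands: CytobandTable, min_fraction: float = 0.99
) -> tuple[bool, str | None]:
    """Detect aneuploidy-scale events: span >= min_fraction of the chromosome.

    Returns (flag, descriptor); the descriptor names the chromosome and the
    direction of the copy-number change.
    """
    length = cytobands.chrom_length(cnv.chrom)
    span = cnv.end - cnv.start + 1
    if span / length < min_fraction:
        return False, None
    direction = "gain" if cnv.variation_type.is_gain else "loss"
    return True, f"whole-chromosome {direction} of chromosome {cnv.chrom}"
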