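"""Genomic interval model and readers/writers for BED, GTF and loop files.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
GTF input (1-based, closed) is converted on read and restored on write, so a
single arithmetic convention holds across all interval operations.  Overlap
arithmetic is strand-agnostic throughout: strand is carried on intervals and
transcripts but never consulted by intersection or merging.  Chromosome names
are matched by exact string equality; :func:`check_shared_chromosomes` warns
when two inputs share no chromosome at all, which usually signals a naming
mismatch ("chr1" vs "1") rather than real disjointness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.iterators import DataIterator

logger = logging.getLogger("ernakit")

__all__ = [
    "GenomicInterval",
    "Transcript",
    "LoopCall",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gtf_transcripts",
    "write_gtf",
    "read_loops",
    "overlap_length",
    "closest_gap",
    "merge_intervals",
    "check_shared_chromosomes",
]


class ParseError(ValueError):
    """Raised on malformed input records; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """A multi-exon transcript with an inferred transcription start site.

    ``tss`` follows the strand rule: leftmost base for '+' (or unstranded)
    transcripts, rightmost base (``span.end - 1``) for '-'.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if any(e.chrom != self.chrom for e in exons):
            raise ValueError(f"transcript {self.transcript_id}: exons on multiple chromosomes")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.strand,
            name=self.transcript_id,
        )

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class LoopCall:
    """A paired-anchor chromatin contact (e.g., a HiChIP enhancer-promoter loop)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float | None = None


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 across chromosomes.

    Half-open convention: book-ended intervals overlap by 0. Strand ignored.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def closest_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Closest-edge distance in bp; 0 when overlapping or abutting.

    Returns None for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or book-ended intervals, per chromosome.

    Matches the default behaviour of ``bedtools merge``: abutting intervals
    ([100,200) + [200,300)) are united.  Strand-agnostic; names and scores of
    inputs are dropped.  Output sorted by (chrom, start).
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def check_shared_chromosomes(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval], label: str = ""
) -> bool:
    """Warn (and return False) when two interval sets share zero chromosome names."""
    chroms_a = {iv.chrom for iv in a}
    chroms_b = {iv.chrom for iv in b}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        logger.warning(
            "no chromosome names shared between inputs%s; check naming conventions "
            "(e.g. 'chr1' vs '1')",
            f" ({label})" if label else "",
        )
        return False
    return True


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED_HEADERS = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; coordinates taken as-is (already half-open).

    Lines starting with '#', 'track' or 'browser' are skipped.  Raises
    :class:`ParseError` naming the line number on malformed records.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_HEADERS):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0 when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf_transcripts(path: str | Path) -> list[Transcript]:
    """Group GTF exon features into transcripts.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Transcript-level features without any exon line are skipped with a
    warning; an exon lacking a ``transcript_id`` attribute is a
    :class:`ParseError`.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    declared: dict[str, bool] = {}
    order: list[str] = []
    for feat in DataIterator(str(path)):
        attrs = feat.attributes
        tids = attrs.get("transcript_id", [])
        if feat.featuretype == "exon":
            if not tids:
                raise ParseError(
                    f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                    "lacks a transcript_id attribute"
                )
            tid = tids[0]
            gene_id = attrs.get("gene_id", [tid])[0]
            if tid not in exons:
                exons[tid] = []
                meta[tid] = (gene_id, feat.seqid, feat.strand)
                order.append(tid)
            exons[tid].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
        elif tids:
            declared.setdefault(tids[0], True)
    for tid in declared:
        if tid not in exons:
            logger.warning("transcript %s has no exon features; skipped", tid)
    out = []
    for tid in order:
        gene_id, chrom, strand = meta[tid]
        out.append(
            Transcript(tid, gene_id, chrom, strand if strand in "+-" else ".", tuple(exons[tid]))
        )
    return out


def write_gtf(transcripts: Sequence[Transcript], path: str | Path, source: str = "ernakit") -> None:
    """Write transcripts as GTF exon (and transcript) features, 1-based closed."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            span = tx.span
            fh.write(
                f"{tx.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for exon in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# paired-anchor loop files
# ---------------------------------------------------------------------------

def read_loops(path: str | Path) -> list[LoopCall]:
    """Read a 6-column paired-anchor file (chrom1 start1 end1 chrom2 start2 end2 [score])."""
    loops: list[LoopCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_HEADERS):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            score = None
            if len(fields) > 6 and fields[6] not in (".", ""):
                try:
                    score = float(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            loops.append(LoopCall(a1, a2, score))
    return loops
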