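"""eRNA identification from a de novo assembled transcriptome.

The pipeline mirrors how enhancer RNAs are called in practice:

1. :func:`filter_transcripts` removes assembled transcripts overlapping
   annotated protein-coding genes, simple repeats or blacklisted regions
   (>= 1 bp, strand-agnostic).
2. :func:`classify_coding` gates the survivors by coding potential — either a
   user-supplied label table from an external classifier run, or a built-in
   longest-ORF rule (coding iff the longest ATG..stop open reading frame is at
   least ``orf_min`` amino acids, default 100 aa).
3. :func:`call_ernas` intersects the remaining non-coding transcripts with
   candidate enhancer regions; by default a transcript is an eRNA when its TSS
   lies inside an enhancer ("transcribed from" an enhancer), with a laxer
   any-overlap rule available.
4. :func:`adjacent_genes` reports putative cis targets within +/- 1 Mb.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enhancers import EnhancerRegion, MarkerSet
from .intervals import GenomicInterval, Transcript, closest_gap, merge_intervals

logger = logging.getLogger("ernakit")

__all__ = [
    "CodingCall",
    "ErnaCall",
    "filter_transcripts",
    "longest_orf_aa",
    "classify_coding",
    "read_coding_table",
    "call_ernas",
    "adjacent_genes",
    "annotate_regions",
    "run_erna_id",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    label: str  # "coding" | "noncoding"
    score: float
    method: str


@dataclass(frozen=True)
class ErnaCall:
    """An identified eRNA: the transcript plus its enhancer evidence."""

    transcript: Transcript
    enhancers: tuple[EnhancerRegion, ...]
    adjacent_genes: tuple[tuple[str, int], ...] = ()
    markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.enhancers:
            raise ValueError("an eRNA call requires at least one supporting enhancer")
        object.__setattr__(self, "enhancers", tuple(self.enhancers))
        object.__setattr__(self, "adjacent_genes", tuple(self.adjacent_genes))
        markers = self.markers or tuple(
            sorted({m for e in self.enhancers for m in e.supporting_markers})
        )
        object.__setattr__(self, "markers", tuple(markers))

    @property
    def erna_id(self) -> str:
        return self.transcript.transcript_id


class _ExclusionIndex:
    """Merged, per-chromosome sorted intervals with bisect overlap queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_left(starts, iv.end)  # first interval starting >= iv.end
        return i > 0 and ends[i - 1] > iv.start


def filter_transcripts(
    transcripts: list[Transcript],
    pcg: list[GenomicInterval],
    repeats: list[GenomicInterval],
    blacklist: list[GenomicInterval],
    exonic: bool = False,
) -> tuple[list[Transcript], list[tuple[str, str]]]:
    """Remove transcripts overlapping any exclusion set (>= 1 bp).

    The removal log records the first matching set in the fixed order
    pcg -> repeats -> blacklist.  By default overlap is tested on the
    transcript span; ``exonic=True`` tests individual exons instead.
    """
    indexes = [
        ("pcg", _ExclusionIndex(pcg)),
        ("repeats", _ExclusionIndex(repeats)),
        ("blacklist", _ExclusionIndex(blacklist)),
    ]
    retained: list[Transcript] = []
    removal_log: list[tuple[str, str]] = []
    for tx in transcripts:
        probes = tx.exons if exonic else (tx.span,)
        reason = next(
            (name for name, idx in indexes if any(idx.overlaps(p) for p in probes)),
            None,
        )
        if reason is None:
            retained.append(tx)
        else:
            removal_log.append((tx.transcript_id, reason))
    return retained, removal_log


# ---------------------------------------------------------------------------
# coding-potential gate
# ---------------------------------------------------------------------------

def longest_orf_aa(sequence: str) -> int:
    """Longest complete ORF (ATG..stop) over the three forward frames, in aa.

    The length counts codons from ATG up to (excluding) the stop, so
    ATG + 99 sense codons + TAA is a 100-aa ORF.  ORFs without an in-frame
    stop codon are not counted.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        orf_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if orf_start is not None:
                    best = max(best, (i - orf_start) // 3)
                    orf_start = None
            elif codon == "ATG" and orf_start is None:
                orf_start = i
    return best


def read_coding_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column (transcript_id, label) TSV from an external classifier."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            label = fields[1].strip().lower()
            if label not in ("coding", "noncoding"):
                raise ValueError(f"{path}:{lineno}: label must be coding/noncoding")
            table[fields[0]] = label
    return table


def classify_coding(
    transcript: Transcript,
    sequence: str | None = None,
    method: str = "orf_fallback",
    orf_min: int = 100,
    table: dict[str, str] | None = None,
) -> CodingCall:
    """Label one transcript coding/noncoding.

    ``orf_fallback`` thresholds the longest forward-strand ORF of the provided
    transcript sequence at ``orf_min`` amino acids.  ``external_table`` looks
    the label up in a precomputed table (e.g. from a dedicated coding-potential
    classifier run outside this package).
    """
    if method == "orf_fallback":
        if sequence is None:
            raise ValueError("orf_fallback requires the transcript sequence")
        if len(sequence) != transcript.exonic_length:
            raise ValueError(
                f"{transcript.transcript_id}: sequence length {len(sequence)} != "
                f"exonic length {transcript.exonic_length}"
            )
        aa = longest_orf_aa(sequence)
        label = "coding" if aa >= orf_min else "noncoding"
        return CodingCall(transcript.transcript_id, label, float(aa), "orf_fallback")
    if method == "external_table":
        if table is None:
            raise ValueError("external_table requires a label table")
        if transcript.transcript_id not in table:
            raise KeyError(
                f"external coding table is missing ids: [{transcript.transcript_id}]"
            )
        return CodingCall(
            transcript.transcript_id,
            table[transcript.transcript_id],
            float("nan"),
            "external_table",
        )
    raise ValueError(f"unknown coding-potential method {method!r}")


# ---------------------------------------------------------------------------
# eRNA calling
# ---------------------------------------------------------------------------

def call_ernas(
    noncoding: list[Transcript],
    enhancers: list[EnhancerRegion],
    rule: str = "tss_in_enhancer",
) -> list[ErnaCall]:
    """Call eRNAs: non-coding transcripts arising from enhancer regions.

    ``tss_in_enhancer`` (default) requires the TSS position to fall inside an
    enhancer interval; ``any_overlap`` accepts >= 1 bp span overlap.  Every
    satisfying enhancer is attached with its supporting markers.
    """
    if rule not in ("tss_in_enhancer", "any_overlap"):
        raise ValueError(f"unknown eRNA call rule {rule!r}")
    calls: list[ErnaCall] = []
    for tx in noncoding:
        span = tx.span
        if rule == "tss_in_enhancer":
            tss = tx.tss
            hits = tuple(
                e
                for e in enhancers
                if e.interval.chrom == tx.chrom and e.interval.start <= tss < e.interval.end
            )
        else:
            hits = tuple(
                e
                for e in enhancers
                if e.interval.chrom == tx.chrom
                and min(e.interval.end, span.end) > max(e.interval.start, span.start)
            )
        if hits:
            calls.append(ErnaCall(tx, hits))
    return calls


def adjacent_genes(
    erna_span: GenomicInterval,
    genes: list[tuple[str, GenomicInterval]],
    window: int = 1_000_000,
) -> list[tuple[str, int]]:
    """Genes whose closest edge lies within ``window`` bp of the eRNA span.

    Distance is the closest-edge gap (0 for overlap or abutment); results are
    sorted by distance then gene id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    hits: list[tuple[str, int]] = []
    for gene_id, iv in genes:
        gap = closest_gap(erna_span, iv)
        if gap is not None and gap <= window:
            hits.append((gene_id, gap))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def annotate_regions(
    ernas: list[ErnaCall], annotations: list[MarkerSet]
) -> pd.DataFrame:
    """Count user-supplied annotation records (mutations, peaks, ...) per eRNA span.

    One row per (eRNA, annotation set), including zero-count rows; overlapping
    record names are comma-joined.
    """
    rows = []
    for call in ernas:
        span = call.transcript.span
        for ann in annotations:
            hits = [
                iv
                for iv in ann.intervals
                if iv.chrom == span.chrom
                and min(iv.end, span.end) > max(iv.start, span.start)
            ]
            rows.append(
                {
                    "erna_id": call.erna_id,
                    "annotation": ann.label,
                    "count": len(hits),
                    "names": ",".join(iv.name or "." for iv in hits),
                }
            )
    return pd.DataFrame(rows, columns=["erna_id", "annotation", "count", "names"])


@dataclass
class ErnaIdResult:
    calls: list[ErnaCall]
    removal_log: list[tuple[str, str]]
    coding_calls: list[CodingCall]
    retained: list[Transcript] = field(default_factory=list)

    @property
    def erna_ids(self) -> set[str]:
        return {c.erna_id for c in self.calls}


def run_erna_id(
    transcripts: list[Transcript],
    pcg: list[GenomicInterval],
    repeats: list[GenomicInterval],
    blacklist: list[GenomicInterval],
    enhancers: list[EnhancerRegion],
    sequences: dict[str, str] | None = None,
    coding_table: dict[str, str] | None = None,
    orf_min: int = 100,
    rule: str = "tss_in_enhancer",
    genes: list[tuple[str, GenomicInterval]] | None = None,
    gene_window: int = 1_000_000,
    exonic: bool = False,
) -> ErnaIdResult:
    """The full identification pipeline: filter, coding gate, eRNA call, targets."""
    from .intervals import check_shared_chromosomes

    spans = [tx.span for tx in transcripts]
    check_shared_chromosomes(spans, pcg, "transcripts vs PCG annotation")
    check_shared_chromosomes(spans, [e.interval for e in enhancers],
                             "transcripts vs enhancers")
    retained, removal_log = filter_transcripts(
        transcripts, pcg, repeats, blacklist, exonic=exonic
    )
    coding_calls: list[CodingCall] = []
    noncoding: list[Transcript] = []
    for tx in retained:
        if coding_table is not None:
            call = classify_coding(tx, method="external_table", table=coding_table)
        elif sequences is not None:
            call = classify_coding(
                tx, sequences[tx.transcript_id], method="orf_fallback", orf_min=orf_min
            )
        else:
            raise ValueError("provide either sequences or a coding_table")
        coding_calls.append(call)
        if call.label == "noncoding":
            noncoding.append(tx)
    calls = call_ernas(noncoding, enhancers, rule=rule)
    if genes:
        calls = [
            ErnaCall(
                c.transcript,
                c.enhancers,
                tuple(adjacent_genes(c.transcript.span, genes, gene_window)),
                c.markers,
            )
            for c in calls
        ]
    return ErnaIdResult(calls, removal_log, coding_calls, retained)
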