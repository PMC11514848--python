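"""Enhancer definition from a "buffet" of marker interval sets.

Enhancer activity can be evidenced by several independent marker types
(H3K27ac / H3K4me1 ChIP-seq peaks, open-chromatin regions, RNAPII binding, or
curated enhancer catalogues).  Each marker interval is expanded to a window of
+/- ``flank`` bp (default 3 kb) around its centre, and the windowed sets are
then combined in one of two modes:

* ``merge`` — the union of all windows: a comprehensive enhancer profile.
* ``overlap`` — only positions covered by at least ``min_support`` distinct
  marker sets: a high-confidence profile.  Fragment boundaries follow
  multi-intersection semantics; adjacent fragments whose supporting label set
  is identical are coalesced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import GenomicInterval, merge_intervals, overlap_length

logger = logging.getLogger("ernakit")

__all__ = ["MarkerSet", "EnhancerRegion", "center_window", "combine_markers"]


@dataclass(frozen=True)
class MarkerSet:
    """A labelled set of enhancer-evidence intervals (one marker type)."""

    label: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("marker label must be non-empty")
        if not self.intervals:
            raise ValueError(f"marker set {self.label!r} has no intervals")
        object.__setattr__(self, "intervals", tuple(self.intervals))


@dataclass(frozen=True)
class EnhancerRegion:
    """A candidate enhancer region with the marker labels supporting it."""

    interval: GenomicInterval
    supporting_markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.supporting_markers:
            raise ValueError("enhancer region must have at least one supporting marker")
        object.__setattr__(self, "supporting_markers", tuple(self.supporting_markers))


def center_window(interval: GenomicInterval, flank: int = 3000) -> GenomicInterval:
    """Window of ``[c - flank, c + flank)`` around the interval's centre.

    The centre of an even-length interval is floored; the left edge is clamped
    at 0 (no right clamp: assembly bounds are optional input).  Name and
    strand are preserved.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    center = (interval.start + interval.end) // 2
    return GenomicInterval(
        interval.chrom,
        max(0, center - flank),
        center + flank,
        interval.strand,
        interval.name,
    )


def _windowed_by_label(
    buffet: list[MarkerSet], flank: int
) -> dict[str, list[GenomicInterval]]:
    """Per-label windowed and merged intervals (each label counts once per base)."""
    out: dict[str, list[GenomicInterval]] = {}
    for ms in buffet:
        if ms.label in out:
            raise ValueError(f"duplicate marker label {ms.label!r} in buffet")
        out[ms.label] = merge_intervals(center_window(iv, flank) for iv in ms.intervals)
    return out


def combine_markers(
    buffet: list[MarkerSet],
    mode: str = "overlap",
    min_support: int = 2,
    flank: int = 3000,
) -> list[EnhancerRegion]:
    """Combine a marker buffet into candidate enhancer regions.

    Every marker interval is centre-windowed with ``flank`` first; windows are
    then combined per ``mode`` (see module docstring).  ``min_support`` applies
    to overlap mode only and counts *distinct marker sets*, not raw intervals.
    An empty result is returned (with a warning), never raised.
    """
    if not buffet:
        raise ValueError("buffet must contain at least one marker set")
    if mode not in ("overlap", "merge"):
        raise ValueError(f"mode must be 'overlap' or 'merge', got {mode!r}")
    windowed = _windowed_by_label(buffet, flank)

    if mode == "overlap":
        if not 1 <= min_support <= len(buffet):
            raise ValueError(
                f"min_support must be in [1, {len(buffet)}], got {min_support}"
            )
        regions = _multi_intersect(windowed, min_support)
    else:
        merged = merge_intervals(iv for ivs in windowed.values() for iv in ivs)
        regions = []
        for region in merged:
            labels = sorted(
                label
                for label, ivs in windowed.items()
                if any(overlap_length(region, iv) > 0 for iv in ivs)
            )
            regions.append(EnhancerRegion(region, tuple(labels)))

    if not regions:
        logger.warning("marker combination produced no enhancer regions")
    return regions


def _multi_intersect(
    windowed: dict[str, list[GenomicInterval]], min_support: int
) -> list[EnhancerRegion]:
    """Boundary sweep: emit maximal runs covered by >= min_support labels.

    Adjacent segments with identical supporting label sets are coalesced;
    a support-set change keeps the fragment boundary (multiinter semantics).
    """
    events: dict[str, list[tuple[int, int, str]]] = {}
    for label, ivs in windowed.items():
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, 1, label))
            events.setdefault(iv.chrom, []).append((iv.end, -1, label))

    regions: list[EnhancerRegion] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom], key=lambda e: (e[0], e[1]))
        active: set[str] = set()
        prev_pos: int | None = None
        current: tuple[int, int, frozenset[str]] | None = None  # open segment
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            if prev_pos is not None and pos > prev_pos and len(active) >= min_support:
                support = frozenset(active)
                if current is not None and current[1] == prev_pos and current[2] == support:
                    current = (current[0], pos, support)
                else:
                    if current is not None:
                        regions.append(_region(chrom, current))
                    current = (prev_pos, pos, support)
            elif current is not None and (prev_pos is None or len(active) < min_support):
                regions.append(_region(chrom, current))
                current = None
            while i < len(evs) and evs[i][0] == pos:
                _, delta, label = evs[i]
                if delta == 1:
                    active.add(label)
                else:
                    active.discard(label)
                i += 1
            prev_pos = pos
        if current is not None:
            regions.append(_region(chrom, current))
    return regions


def _region(chrom: str, seg: tuple[int, int, frozenset[str]]) -> EnhancerRegion:
    start, end, support = seg
    return EnhancerRegion(GenomicInterval(chrom, start, end), tuple(sorted(support)))
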