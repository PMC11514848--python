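"""Synthetic data generators for the whole toolkit.

Every input the pipeline consumes — toy genome annotation with planted eRNAs
and decoys, marker BEDs, coverage tracks with known read placements,
expression matrices with planted rank correlation, peak/loop files and GMT
gene sets — can be generated offline from a :class:`FixtureSpec`.  Each
generator is a pure function of the spec (and its explicit arguments): the
same seed yields byte-identical files.  Truth tables label every planted
feature so downstream stages can be scored without re-deriving ground truth.

The genome layout places each feature in its own non-overlapping 20-kb slot
along the chromosome, so planted eRNAs never collide with exclusion regions
by accident and distal decoys are guaranteed to sit outside every +/-3 kb
marker window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enhancers import MarkerSet
from .intervals import GenomicInterval, Transcript, write_bed, write_gtf
from .quantify import CoverageTrack, LibraryStats, write_bedgraph

__all__ = [
    "FixtureSpec",
    "preset",
    "AnnotationFixture",
    "make_annotation",
    "ExpressionFixture",
    "make_expression",
    "TracksFixture",
    "make_tracks_and_reads",
]

SLOT_WIDTH = 20_000
_STOP_BLOCK = "TAGATAGATAGA"  # stop codon within <= 4 codons in every frame
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic data; the seed determines every byte."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_pcg: int = 20
    n_noncoding: int = 10  # decoy transcripts (repeat/blacklist/coding/distal cycle)
    n_planted_ernas: int = 8
    n_samples: int = 50
    planted_rho: float = 0.8
    noise_sd: float = 1.0
    fraction_null: float = 0.96

    def __post_init__(self) -> None:
        for name in ("n_pcg", "n_noncoding", "n_planted_ernas", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.planted_rho < 1.0:
            raise ValueError("planted_rho must lie in (-1, 1)")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must lie in [0, 1]")


def preset(name: str, seed: int = 0) -> FixtureSpec:
    """Named study conditions: 'tiny', 'default' or 'network-heavy'."""
    if name == "tiny":
        return FixtureSpec(
            seed=seed,
            chrom_sizes={"chr1": 300_000},
            n_pcg=5,
            n_noncoding=4,
            n_planted_ernas=3,
            n_samples=12,
        )
    if name == "default":
        return FixtureSpec(seed=seed)
    if name == "network-heavy":
        # 20 planted pairs among the 20 x 26 = 520 (eRNA, PCG) pairs
        return FixtureSpec(
            seed=seed,
            n_pcg=26,
            n_noncoding=10,
            n_planted_ernas=20,
            n_samples=50,
            planted_rho=0.8,
            fraction_null=1.0 - 20 / 520,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a stop codon in every frame at least every ~40 nt,
    so no ORF approaches the coding threshold."""
    parts: list[str] = []
    total = 0
    while total < length:
        take = min(30, length - total)
        block = "".join(_BASES[i] for i in rng.integers(0, 4, size=take))
        parts.append(block)
        total += take
        if total < length:
            stop = _STOP_BLOCK[: min(len(_STOP_BLOCK), length - total)]
            parts.append(stop)
            total += len(stop)
    return "".join(parts)


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """Sequence carrying one long ORF (>= 100 aa when length permits)."""
    orf_codons = min(120, (length - 3) // 3 - 1)
    if orf_codons < 2:
        raise ValueError(f"length {length} too short for a coding sequence")
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=orf_codons - 1)
    )
    core = "ATG" + body + "TAA"
    pad = length - len(core)
    left = pad // 2
    return _noncoding_seq(rng, left) + core + _noncoding_seq(rng, pad - left)


# ---------------------------------------------------------------------------
# genome annotation with planted eRNAs
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixture:
    spec: FixtureSpec
    transcripts: list[Transcript]  # the "de novo assembled" transcriptome
    sequences: dict[str, str]
    pcg_reference: list[Transcript]
    genes: list[tuple[str, GenomicInterval]]
    pcg_intervals: list[GenomicInterval]
    repeats: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    markers: list[MarkerSet]
    truth: pd.DataFrame  # columns: transcript_id, label in {planted_erna, decoy, pcg}

    @property
    def planted_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["label"] == "planted_erna", "transcript_id"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, outdir / "transcripts.gtf")
        write_gtf(self.pcg_reference, outdir / "pcg.gtf")
        write_bed(self.repeats, outdir / "repeats.bed")
        write_bed(self.blacklist, outdir / "blacklist.bed")
        for ms in self.markers:
            write_bed(list(ms.intervals), outdir / f"marker_{ms.label}.bed")
        with open(outdir / "transcripts.fa", "w") as fh:
            for tx in self.transcripts:
                fh.write(f">{tx.transcript_id}\n{self.sequences[tx.transcript_id]}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _transcript_in_slot(
    rng: np.random.Generator, tid: str, chrom: str, center: int
) -> Transcript:
    """A 1- or 2-exon transcript whose TSS falls within +/-2 kb of ``center``."""
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    length = int(rng.integers(400, 1201))
    offset = int(rng.integers(-2000, 2001))
    tss = center + offset
    two_exon = rng.integers(0, 2) == 1
    gap = int(rng.integers(50, 201)) if two_exon else 0
    total = length + gap
    if strand == "+":
        left = tss
    else:
        left = tss - total + 1
    if two_exon:
        a = length // 2
        exons = (
            GenomicInterval(chrom, left, left + a, strand),
            GenomicInterval(chrom, left + a + gap, left + total, strand),
        )
    else:
        exons = (GenomicInterval(chrom, left, left + length, strand),)
    return Transcript(tid, tid, chrom, strand, exons)


def make_annotation(spec: FixtureSpec) -> AnnotationFixture:
    """Generate the toy genome: PCG annotation, exclusion regions, two marker
    sets defining enhancer loci, planted eRNAs and decoy transcripts.

    The assembled transcriptome contains one re-assembled copy of each PCG
    (labelled ``pcg`` in the truth table), ``n_planted_ernas`` non-coding
    transcripts whose TSS sits inside a marker-derived enhancer window
    (``planted_erna``), and ``n_noncoding`` decoys cycling through four
    failure modes: repeat overlap, blacklist overlap, coding sequence inside
    an enhancer, and a clean ncRNA far from every enhancer (all ``decoy``).
    """
    rng = np.random.default_rng(spec.seed)
    chrom = sorted(spec.chrom_sizes)[0]
    chrom_size = spec.chrom_sizes[chrom]

    decoy_kinds = ["repeat", "blacklist", "coding", "distal"]
    decoys = [decoy_kinds[i % 4] for i in range(spec.n_noncoding)]
    n_coding = decoys.count("coding")

    roles: list[tuple[str, int]] = []
    roles += [("pcg", i) for i in range(spec.n_pcg)]
    roles += [("enhancer", i) for i in range(spec.n_planted_ernas)]
    roles += [("enhancer_coding", i) for i in range(n_coding)]
    roles += [("enhancer_bg", 0)]  # background enhancer locus with no transcript
    roles += [("repeat", i) for i in range(max(1, decoys.count("repeat")))]
    roles += [("blacklist", i) for i in range(max(1, decoys.count("blacklist")))]
    roles += [("distal", i) for i in range(decoys.count("distal"))]

    if len(roles) * SLOT_WIDTH > chrom_size:
        raise ValueError(
            f"chromosome {chrom} ({chrom_size} bp) too small for "
            f"{len(roles)} feature slots of {SLOT_WIDTH} bp; enlarge chrom_sizes"
        )
    order = rng.permutation(len(roles))
    centers = {tuple(roles[int(j)]): int(i) * SLOT_WIDTH + SLOT_WIDTH // 2
               for i, j in enumerate(order)}

    pcg_reference: list[Transcript] = []
    genes: list[tuple[str, GenomicInterval]] = []
    transcripts: list[Transcript] = []
    sequences: dict[str, str] = {}
    truth_rows: list[tuple[str, str]] = []
    repeats: list[GenomicInterval] = []
    blacklist: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    atac: list[GenomicInterval] = []

    for i in range(spec.n_pcg):
        c = centers[("pcg", i)]
        gid = f"GENE{i + 1}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        exons = (
            GenomicInterval(chrom, c - 2500, c - 1000, strand),
            GenomicInterval(chrom, c - 500, c + 1500, strand),
        )
        ref = Transcript(f"{gid}.1", gid, chrom, strand, exons)
        pcg_reference.append(ref)
        genes.append((gid, ref.span))
        asm = Transcript(f"ASM-PCG{i + 1}", f"ASM-PCG{i + 1}", chrom, strand, exons)
        transcripts.append(asm)
        sequences[asm.transcript_id] = _coding_seq(rng, asm.exonic_length)
        truth_rows.append((asm.transcript_id, "pcg"))

    enhancer_slots = (
        [("enhancer", i) for i in range(spec.n_planted_ernas)]
        + [("enhancer_coding", i) for i in range(n_coding)]
        + [("enhancer_bg", 0)]
    )
    for key in enhancer_slots:
        c = centers[key]
        h3k27ac.append(GenomicInterval(chrom, c - 250, c + 250, name=f"K27_{c}"))
        atac.append(GenomicInterval(chrom, c - 150, c + 150, name=f"ATAC_{c}"))

    for i in range(spec.n_planted_ernas):
        c = centers[("enhancer", i)]
        tx = _transcript_in_slot(rng, f"ERNA{i + 1}", chrom, c)
        transcripts.append(tx)
        sequences[tx.transcript_id] = _noncoding_seq(rng, tx.exonic_length)
        truth_rows.append((tx.transcript_id, "planted_erna"))

    counters = {"repeat": 0, "blacklist": 0, "coding": 0, "distal": 0}
    for kind in decoys:
        idx = counters[kind]
        counters[kind] += 1
        tid = f"DECOY-{kind.upper()}{idx + 1}"
        if kind == "coding":
            c = centers[("enhancer_coding", idx)]
            tx = _transcript_in_slot(rng, tid, chrom, c)
            seq = _coding_seq(rng, tx.exonic_length)
        elif kind == "distal":
            c = centers[("distal", idx)]
            tx = _transcript_in_slot(rng, tid, chrom, c)
            seq = _noncoding_seq(rng, tx.exonic_length)
        else:  # repeat / blacklist overlap
            c = centers[(kind, idx)]
            exon = GenomicInterval(chrom, c + 300, c + 1300, "+")
            tx = Transcript(tid, tid, chrom, "+", (exon,))
            seq = _noncoding_seq(rng, tx.exonic_length)
        transcripts.append(tx)
        sequences[tid] = seq
        truth_rows.append((tid, "decoy"))

    for i in range(max(1, decoys.count("repeat"))):
        c = centers[("repeat", i)]
        repeats.append(GenomicInterval(chrom, c - 500, c + 500, name=f"rpt{i + 1}"))
    for i in range(max(1, decoys.count("blacklist"))):
        c = centers[("blacklist", i)]
        blacklist.append(GenomicInterval(chrom, c - 500, c + 500, name=f"bl{i + 1}"))

    markers = [
        MarkerSet("H3K27ac", tuple(sorted(h3k27ac, key=lambda iv: iv.start))),
        MarkerSet("ATAC", tuple(sorted(atac, key=lambda iv: iv.start))),
    ]
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "label"])
    return AnnotationFixture(
        spec=spec,
        transcripts=transcripts,
        sequences=sequences,
        pcg_reference=pcg_reference,
        genes=genes,
        pcg_intervals=[tx.span for tx in pcg_reference],
        repeats=repeats,
        blacklist=blacklist,
        markers=markers,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression matrices with planted rank correlation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionFixture:
    erna_expr: pd.DataFrame
    pcg_expr: pd.DataFrame
    planted_pairs: list[tuple[str, str]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.erna_expr.to_csv(outdir / "erna_expr.tsv", sep="\t")
        self.pcg_expr.to_csv(outdir / "pcg_expr.tsv", sep="\t")
        pd.DataFrame(self.planted_pairs, columns=["erna", "pcg"]).to_csv(
            outdir / "planted_pairs.tsv", sep="\t", index=False
        )


def make_expression(
    spec: FixtureSpec, erna_ids: list[str], pcg_ids: list[str]
) -> ExpressionFixture:
    """Expression matrices with planted (eRNA, PCG) rank correlation.

    Planted pairs share a latent Gaussian; the mixing weight uses the exact
    Gaussian-copula inversion r = 2*sin(pi*rho_s/6), so the expected Spearman
    correlation of a planted pair equals ``spec.planted_rho``.  Each feature
    participates in at most one planted pair; all other features are
    independent noise (sd ``noise_sd``), so every non-planted pair is null.
    The number of planted pairs is
    ``round((1 - fraction_null) * |eRNAs| * |PCGs|)``.
    """
    if spec.n_samples < 10:
        raise ValueError("need n_samples >= 10")
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_samples
    total = len(erna_ids) * len(pcg_ids)
    n_pairs = min(
        round((1.0 - spec.fraction_null) * total), len(erna_ids), len(pcg_ids)
    )
    pairs = list(zip(erna_ids[:n_pairs], pcg_ids[:n_pairs]))

    r = 2.0 * math.sin(math.pi * spec.planted_rho / 6.0)
    a = math.sqrt(abs(r))
    b = math.sqrt(1.0 - abs(r))
    sign = 1.0 if r >= 0 else -1.0

    erna_rows = np.empty((len(erna_ids), n))
    pcg_rows = np.empty((len(pcg_ids), n))
    for i in range(n_pairs):
        z = rng.standard_normal(n)
        erna_rows[i] = a * z + b * rng.standard_normal(n)
        pcg_rows[i] = sign * a * z + b * rng.standard_normal(n)
    for i in range(n_pairs, len(erna_ids)):
        erna_rows[i] = spec.noise_sd * rng.standard_normal(n)
    for i in range(n_pairs, len(pcg_ids)):
        pcg_rows[i] = spec.noise_sd * rng.standard_normal(n)

    samples = [f"S{i + 1}" for i in range(n)]
    return ExpressionFixture(
        erna_expr=pd.DataFrame(erna_rows, index=list(erna_ids), columns=samples),
        pcg_expr=pd.DataFrame(pcg_rows, index=list(pcg_ids), columns=samples),
        planted_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# coverage tracks from explicit read placements
# ---------------------------------------------------------------------------

@dataclass
class TracksFixture:
    tracks: dict[str, CoverageTrack]
    stats: dict[str, LibraryStats]
    counts: pd.DataFrame  # regions x samples, true read counts

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, track in self.tracks.items():
            write_bedgraph(track, outdir / f"{sample}.bedgraph")
        pd.DataFrame(
            [
                (s, st.read_length, st.total_mapped_reads)
                for s, st in self.stats.items()
            ],
            columns=["sample", "read_length", "total_mapped_reads"],
        ).to_csv(outdir / "library_stats.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "true_counts.tsv", sep="\t")


def make_tracks_and_reads(
    spec: FixtureSpec,
    regions: list[tuple[str, GenomicInterval]],
    read_length: int = 100,
    mean_reads: int = 400,
    contained: bool = True,
    n_samples: int | None = None,
    counts: np.ndarray | None = None,
) -> TracksFixture:
    """Per-sample coverage tracks from uniformly placed reads with known counts.

    ``contained=True`` places every read fully inside its region, so
    sum(Cov) = count * R exactly and coverage FPKM equals count FPKM.
    ``contained=False`` places read 5' ends uniformly inside the region, so
    reads starting within the last R-1 bases run past the 3' edge; the
    uncredited overhang bounds the relative FPKM error by (R-1)/L.
    ``counts`` (regions x samples) overrides the Poisson(``mean_reads``) draw.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    for rid, region in regions:
        if len(region) < read_length:
            raise ValueError(
                f"region {rid} ({len(region)} bp) shorter than read length {read_length}"
            )
    rng = np.random.default_rng([spec.seed, 2])
    n_samples = spec.n_samples if n_samples is None else n_samples
    samples = [f"S{i + 1}" for i in range(n_samples)]
    if counts is None:
        counts = rng.poisson(mean_reads, size=(len(regions), n_samples))
    else:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(regions), n_samples):
            raise ValueError("counts must have shape (n_regions, n_samples)")

    tracks: dict[str, CoverageTrack] = {}
    stats: dict[str, LibraryStats] = {}
    for j, sample in enumerate(samples):
        diffs: dict[str, np.ndarray] = {}
        for i, (_, region) in enumerate(regions):
            size = spec.chrom_sizes.get(region.chrom)
            if size is None:
                raise ValueError(f"chromosome {region.chrom} absent from chrom_sizes")
            diff = diffs.setdefault(region.chrom, np.zeros(size + 1, dtype=np.int64))
            if contained:
                starts = rng.integers(
                    region.start, region.end - read_length + 1, size=counts[i, j]
                )
            else:
                starts = rng.integers(region.start, region.end, size=counts[i, j])
            np.add.at(diff, np.clip(starts, 0, size), 1)
            np.add.at(diff, np.clip(starts + read_length, 0, size), -1)
        steps: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, diff in diffs.items():
            depth = np.cumsum(diff[:-1])
            edges = np.flatnonzero(np.diff(depth)) + 1
            bounds = np.concatenate(([0], edges, [len(depth)]))
            runs = [
                (int(s), int(e), float(depth[s]))
                for s, e in zip(bounds[:-1], bounds[1:])
                if depth[s] > 0
            ]
            if runs:
                steps[chrom] = runs
        tracks[sample] = CoverageTrack(steps)
        stats[sample] = LibraryStats(read_length, int(counts[:, j].sum()))

    return TracksFixture(
        tracks=tracks,
        stats=stats,
        counts=pd.DataFrame(counts, index=[rid for rid, _ in regions], columns=samples),
    )
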