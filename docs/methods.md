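# Methods

This note documents the models and procedures implemented in ernakit, the
defaults that matter, the numerical choices, and what the synthetic fixtures
do and do not emulate.

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`. GTF input
(1-based closed) is converted on read and restored on write. Overlap,
merging and multi-intersection are strand-agnostic everywhere: strand is
carried (and drives TSS inference) but never consulted by interval
arithmetic. Book-ended intervals merge, matching the `bedtools merge`
default. Chromosome names are compared by exact string equality — no
"chr1"/"1" aliasing — and a preflight helper warns when two inputs share
zero chromosome names, which almost always indicates a naming mismatch
rather than real disjointness.

## Enhancer definition

Enhancer evidence arrives as one or more labelled marker interval sets.
Each interval is expanded to `[c − flank, c + flank)` around its centre
`c = ⌊(start + end)/2⌋` (flank default 3000 bp; the floored centre makes the
window deterministic for even-length intervals; the left edge clamps at 0,
and no right clamp is applied because assembly bounds are optional input).
Windowing happens *per marker, before combination* — the window belongs to
the marker, not to the combined product — and all marker types are windowed
uniformly.

Two combination modes:

* **merge** — union of all windows; each merged region lists every marker
  label that intersects it. Comprehensive, lower confidence.
* **overlap** — a boundary sweep keeps positions covered by at least
  `min_support` *distinct* marker sets (default 2; per-label windows are
  pre-merged so one marker type never counts twice at a base). Fragment
  boundaries follow multi-intersection semantics: a change in the supporting
  label set starts a new fragment, and adjacent fragments with identical
  support are coalesced.

Overlap-mode output is positionwise a subset of merge-mode output, and at
`min_support = 1` the two cover identical positions; both facts are
property-tested against a per-base counting oracle.

## eRNA identification

Filtering removes a transcript whose span overlaps any PCG, simple-repeat
or blacklist interval by ≥ 1 bp. Span-level overlap is the default
(conservative removal); `exonic=True` restricts the test to exons, which
retains transcripts whose only conflict is intronic. The removal log records
the first matching set in the fixed order pcg → repeats → blacklist; the
order affects logs only, never the retained set.

The coding gate is pluggable. The external-table route consumes a 2-column
(id, label) file from any dedicated classifier run outside the package. The
built-in rule scans the three forward frames of the transcript sequence for
the longest complete ATG..stop ORF and labels the transcript coding when
that ORF is ≥ `orf_min` amino acids (default 100 aa, the conventional
long-ORF cutoff for lncRNA discrimination; the aa count includes the
initiator Met and excludes the stop). ORFs without an in-frame stop are not
counted — an open-ended ORF in a truncated assembly is not treated as
evidence of coding capacity.

The default call rule is `tss_in_enhancer`: a non-coding transcript is an
eRNA iff its TSS (strand-aware: left edge on +/unstranded, `end − 1` on −)
lies inside an enhancer region. This reads "transcribed from an enhancer" as
origin of transcription. The laxer `any_overlap` rule (span overlap ≥ 1 bp)
is a strict superset and is exposed as a flag. Adjacent genes are reported
within ± 1 Mb using closest-edge distance (0 for overlap or abutment); ties
sort by gene id. Arbitrary user BEDs (mutations, histone peaks, ...) can be
counted per eRNA span with the generic region-annotation operation,
including explicit zero-count rows.

## Coverage-based FPKM

Expression is estimated from a coverage step function (bedGraph) instead of
read counting: `FPKM = Σ(Cov) · 10⁹ / (R · L · T)` with Σ(Cov) the summed
depth × overlap over the region, R the read length, L the region length
(exonic length for transcripts, with coverage summed over exons only), and T
total mapped reads. For paired-end libraries R is the mean mapped read
length and T counts mapped reads, not fragments. The estimator is linear in
Σ(Cov) and inverse-linear in R, L, T.

Relation to count-based FPKM (`count · 10⁹ / (L · T)`): a read fully inside
the region contributes exactly R bases of coverage, so the two estimators
coincide; a read overhanging the region boundary contributes only its
overlap, making coverage FPKM a slight underestimate. For reads whose 5'
ends lie inside the region, the overhang deficit is at most `(R − 1)/L`
relative — the generator's straddle mode uses exactly this placement so the
bound is testable (expected deficit `(R − 1)/2L`, half the bound). bedGraph
is the required input because it is text and encodes the step function
exactly; tracks with overlapping runs are rejected at construction.

## Co-expression network

For every (eRNA, PCG) pair — deliberately not PCG×PCG — Spearman's ρ is the
Pearson correlation of mid-ranks (average ranks on ties), computed as one
standardized matrix product. Two-sided p-values use the
`t = ρ·√((n−2)/(1−ρ²))` approximation on n − 2 df, which is standard beyond
n ≈ 10; ρ = ±1 maps to p = 0, and |ρ| within 1e-13 of 1 is snapped to ±1 so
perfectly monotone pairs are not lost to float roundoff. Zero-variance
features yield ρ = p = NaN and are excluded downstream. For n ≤ 9 an exact
permutation p (fraction of all n! orderings with |ρ| at least the observed,
a ≥-rule with 1e-12 slack) is available; at n = 4 and ρ = 0.8 the exact
two-sided p is 8/24 = 1/3 while the t approximation gives ≈ 0.20 — the
documented divergence case, frozen in the tests.

Multiple testing defaults to Benjamini–Hochberg (step-up, NaNs excluded
from the family size and propagated), with Bonferroni as an option;
adjustment is global across all computed pairs by default, per-eRNA by
flag. Edges are kept at |ρ| ≥ 0.3 and q ≤ 0.05 — conventional, user-visible
thresholds — and the network keeps only endpoint nodes of surviving edges,
with co-expression edges canonicalized to lexicographic endpoint order
(roles, not orientation, record which endpoint is the eRNA).

## Regulatory network and intersection

A TF or RBP becomes a regulator of an eRNA when ≥ 1 of its peaks overlaps
the eRNA span (≥ 1 bp, half-open: book-ended peaks do not count); the edge's
evidence field records the peak count. A loop links an eRNA to a gene when
one anchor overlaps the eRNA span and the other overlaps the gene's promoter
window `[tss − 2000, tss + 2000)`; ± 2 kb is the package's choice of
promoter extent for resolving a loop's gene end. Loops touching an eRNA
without reaching any promoter are reported separately as eRNA-mediated
loops. Network intersection takes shared node ids and shared *unordered*
node pairs; edge kinds may differ between inputs and both are recorded in
the evidence. Intersection is commutative and idempotent and its edge set is
a subset of both inputs (property-tested).

## Module extraction and hubs

Modules come from a greedy seed-and-expand clustering of the unweighted
simple graph (parallel edges of different kinds collapse to one): seed at
the unclustered node of highest degree, pair it with its best unclustered
neighbour — in an unweighted graph all neighbours tie, so the lexicographic
smallest id is taken, which makes the procedure deterministic — then
repeatedly add the candidate with the highest *support* (fraction of current
members it connects to), accepting while support ≥ 0.5 and the resulting
density `2·E/(k(k−1))` stays ≥ 0.5. Emitted clusters are removed and the
process repeats while edges remain; singletons are discarded. Every emitted
module therefore satisfies the density floor, and modules are pairwise
disjoint. On two 4-cliques joined by a single bridge edge the procedure
returns exactly the two cliques.

"Hub" has no canonical definition; the package uses a degree-quantile rule:
nodes with degree ≥ max(`min_degree` = 5, the (1 − 0.05) degree quantile),
sorted by degree then id. Both knobs are exposed.

## Enrichment

Over-representation uses the upper-tail hypergeometric
`p = P(X ≥ k) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n)` with N the universe size, K the
set size, n the query size, k the overlap. Gene sets are restricted to the
universe at construction; query ids outside the universe are dropped with a
warning. q-values are BH *within each collection* (GO, KEGG and hallmark
files are adjusted separately when run separately). The default universe is
the union of the GMT's genes and the network's PCGs; network-only or
file-based universes are flags. An eRNA is annotated through three queries —
PCG neighbours, PCG members of each containing module, PCG hubs among its
neighbours — each enriched independently.

## Synthetic fixtures

The generators are pure functions of a `FixtureSpec`; a seed fixes every
output byte. The toy genome places each feature in its own 20-kb slot in a
seed-permuted order, so planted eRNAs can never collide with exclusion
regions by construction and distal decoys are provably outside every ± 3 kb
marker window; infeasible slot counts raise an error suggesting a larger
chromosome. Planted eRNA TSSs fall within ± 2 kb of a marker centre (inside
the ± 3 kb enhancer window); decoys cycle through repeat-overlap,
blacklist-overlap, coding-inside-enhancer and distal-clean failure modes,
and each PCG contributes a re-assembled transcript copy to the "novel"
GTF. Non-coding sequences interleave random 30-mers with a block carrying a
stop codon in every frame (capping ORFs at ~14 aa); coding sequences embed
one ≥ 100-codon ORF.

Planted expression pairs share a latent Gaussian with mixing weight chosen
by the exact Gaussian-copula inversion `r = 2·sin(π·ρ_s/6)`, so a planted
pair's *expected* Spearman correlation equals `planted_rho` without
per-seed calibration; all other features are independent noise, so every
non-planted pair is null. Coverage fixtures place reads uniformly (fully
contained, or 5'-inside with 3' overhang) and return exact tracks plus true
counts, so the coverage and counting FPKM routes cross-validate.

What the fixtures do **not** emulate: read errors, GC/mappability bias,
multimapping, overdispersed or zero-inflated expression marginals,
correlated null structure (batch effects), or realistic genome geometry
(overlapping genes, nested repeats). Passing tests therefore demonstrate
correctness of the interval logic, estimators and algorithms under clean
planted conditions — not robustness to the confounders of real libraries.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design: the
tiny genome (300 kb, 12 transcripts), 100 quantification regions, 50 random
20 × 12 correlation matrices, 1000 BH vectors, 20 co-expression seeds at
20 planted/500 null pairs and n = 50 samples, 200 random graphs for module
checks, and full hypergeometric enumeration for N ≤ 25. All randomness flows
through explicit seeds; hypothesis-based property tests are derandomized.

## Known limitations

* Single-species, annotation-version-agnostic: the toolkit never checks
  that inputs share a genome build beyond chromosome-name overlap.
* The ORF gate is a deliberate simplification of ML-based coding-potential
  classifiers; users wanting CPC2-class accuracy should supply an external
  label table.
* No BigWig reader is wired in (bedGraph only), and no multimapping or
  fragment-level correction is applied in quantification.
* Exact permutation p-values cost n! per pair and are restricted to n ≤ 9.
* Module extraction is greedy: it inherits SPICi's determinism and speed
  but, like the original, does not guarantee globally optimal clusters.
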