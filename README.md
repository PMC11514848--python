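# ernakit

Offline toolkit for **enhancer RNA (eRNA) analysis**: identify eRNAs in a
de novo assembled transcriptome using user-supplied enhancer markers, then
characterise each eRNA's interactome — co-expressed protein-coding genes
(PCGs), overlapping TF/RBP peaks, enhancer–promoter loops — and infer its
function by dense-module extraction and hypergeometric gene-set enrichment.

It is aimed at regulatory-genomics analysts who have a StringTie/Cufflinks
GTF from RNA-seq or GRO-seq plus local evidence of enhancer activity
(H3K27ac/H3K4me1 peaks, ATAC/DNase regions, RNAPII binding, or curated
enhancer catalogues in BED format) and want a scriptable, fully local
pipeline with no hosted datasets.

## Method

**Identification.** Assembled transcripts are removed if their span overlaps
(≥ 1 bp, strand-agnostic) an annotated PCG, a simple repeat or a blacklisted
region. Survivors are gated by coding potential — an external classifier's
label table, or the built-in rule *coding ⇔ longest ATG..stop ORF ≥ 100 aa*.
Enhancer regions come from a "marker buffet": each marker interval is
expanded to ± 3 kb around its centre, and the windowed sets are either
**merged** (comprehensive union) or **overlapped** (positions labelled by ≥ k
distinct marker types, high confidence). A non-coding transcript whose TSS
falls inside an enhancer region is called an eRNA (an any-overlap rule is
available), and genes within ± 1 Mb are reported as putative cis targets.

**Quantification.** Expression is estimated from base-level coverage rather
than read counting:

    FPKM = Σ(Cov) · 10⁹ / (R · L · T)

with Σ(Cov) the summed per-base coverage over the region, R the read length,
L the region (or exonic) length, and T the library's total mapped reads. For
reads fully contained in the region this equals count-based FPKM exactly.

**Interactome.** Co-expression edges are Spearman correlations (mid-ranks,
two-sided p from the t approximation, exact permutation p optional for
n ≤ 9) between every (eRNA, PCG) pair, Benjamini–Hochberg adjusted and
thresholded at |ρ| ≥ 0.3, q ≤ 0.05 by default. Regulatory edges come from
TF/RBP peaks inside eRNA spans and from loops with one anchor on the eRNA
and the other on a gene promoter (TSS ± 2 kb). Two networks can be
intersected (shared nodes, shared unordered edges) for high-confidence
interactions.

**Annotation.** Dense modules are extracted with a greedy seed-and-expand
clustering (unweighted SPICi-style: density ≥ 0.5, support ≥ 0.5), hubs by
degree quantile, and each eRNA is annotated by upper-tail hypergeometric
enrichment (P(X ≥ k) over a finite gene universe) of its PCG neighbours,
module co-members and adjacent hubs against GMT gene sets.

A synthetic-fixture module generates every input format with planted ground
truth, so the whole pipeline runs and is testable offline.

## Worked example

Generate a tiny planted genome (5 PCGs, 3 planted eRNAs, 4 decoys) and run
identification and quantification:

```bash
erna fixtures --out demo --seed 1 --preset tiny
erna buffet --marker H3K27ac=demo/marker_H3K27ac.bed --marker ATAC=demo/marker_ATAC.bed \
     --mode overlap --min-support 2 --out demo/enhancers.bed
erna id --transcripts demo/transcripts.gtf --pcg demo/pcg.gtf \
     --repeats demo/repeats.bed --blacklist demo/blacklist.bed \
     --enhancers demo/enhancers.bed --sequences demo/transcripts.fa \
     --out demo/ernas.tsv
erna quantify --regions demo/ernas.bed --track S1=demo/S1.bedgraph \
     --stats S1=R:100,T:1000000 --out demo/fpkm.tsv
```

which prints

```
5 enhancer regions -> demo/enhancers.bed
3 eRNAs called from 12 transcripts (7 removed by filters) -> demo/ernas.tsv
FPKM matrix 3 regions x 1 samples -> demo/fpkm.tsv
```

`demo/ernas.tsv` lists each call with its enhancer, markers and ranked
adjacent genes:

```
transcript_id  chrom  start   end     strand  enhancers           markers        adjacent_genes
ERNA1          chr1   127388  128460  -       chr1:127000-133000  ATAC,H3K27ac   GENE5:15888;GENE1:39040;...
ERNA2          chr1   228842  229871  +       chr1:227000-233000  ATAC,H3K27ac   GENE4:17629;GENE3:37342;...
ERNA3          chr1   49816   50912   -       chr1:47000-53000    ATAC,H3K27ac   GENE2:38316;GENE5:56588;...
```

The 3 called eRNAs are exactly the planted ones in `demo/truth.tsv`; the 7
filtered transcripts are the 5 re-assembled PCG copies plus the
repeat/blacklist decoys, and the coding and distal decoys fall to the ORF
gate and the enhancer rule. `demo/fpkm.tsv` holds the coverage-based FPKM
values (e.g. ERNA1: 370.3 at R = 100, T = 10⁶). Co-expression, module and
enrichment stages run the same way via `erna coexpr`, `erna regnet`,
`erna combine` and `erna annotate` — see `erna <cmd> --help`.

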