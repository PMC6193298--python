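# Methods

This note documents the models and procedures `holoseq` implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout.

## Coordinates and quantification

All internal coordinates are 0-based half-open; GTF input (1-based,
inclusive) is converted at the boundary. Multi-isoform genes are collapsed
to the union of their transcript exons per `gene_id`; introns are the gaps
between merged exons.

Read counting is per gene and per region: a unique-mapped read counts once
if any aligned block (spliced alignments contribute each block) overlaps the
region by ≥ 1 bp on the required strand. A read touching both exon and
intron counts to the exon only — the counts are disjoint, and exonic signal
dominates boundary fragments. In strand-aware mode a read counts to every
same-strand overlapping gene; no further disambiguation is attempted.

Normalization: `RPKM = count / (L/10³) / (T/10⁶)` with `L` the merged exon
length and `T` the library's mapped total; `RPM = count / (T/10⁶)` for
length-free small-RNA features. Expressed-feature filters follow two rules,
with "larger than" read strictly and "at least" inclusively: mean RPKM
> 0.1 across libraries, or ≥ 10 reads in ≥ 1 library together with RPKM
> 0.1 in ≥ 1 library.

Carrier accounting partitions reads whose source is the carrier reference;
removal efficiency is the fraction of true carrier reads removed, defined
as 1.0 (vacuous success) when no carrier reads exist. The carrier's
removability rests on its engineered Not I sites; `count_restriction_sites`
reports all (including overlapping) occurrences of `GCGGCCGC`.

## The degenerate-barcode model

Libraries amplified with primers carrying an 8-nt degenerate barcode
(`4⁸ = 65,536` barcodes) are deduplicated by counting distinct barcodes per
mapped position, where a position is `(chrom, 5′-most aligned coordinate,
strand)` — the 5′ endpoint identifies the fragment. Gene-level barcoded
counts sum the per-position counts over exonic positions.

Two closed forms characterize the model. The per-position collision
probability among `n` independently, uniformly barcoded molecules is the
birthday product `1 − Π_{i=1}^{n−1}(1 − i/B)`; at the observed ceiling of
~10 molecules per position it is `6.86 × 10⁻⁴`, comfortably below 0.01, so
distinct-barcode counts are essentially exact molecule counts. The
amplification ceiling is `max_templates × 2^cycles` distinct barcoded reads
per position (10,240 for 10 templates and 10 cycles): each template draws
one barcode at priming and every cycle doubles every fragment.

## Gene-body coverage (BCI)

Per gene, per-bp coverage along the merged exons is divided by the gene's
exonic read count, the exons are split into 100 near-equal bins
(largest-remainder allocation: bins differ by ≤ 1 bp, the remainder goes to
the last bins), and per-bin sums are divided by bin length. Genes are
grouped by total exon length (0–2, 2–4, 4–6, 10–12 kb, plus the overlapping
6 kb-up and 12 kb-up reporting groups, half-open intervals); the per-bin sum
across a group is normalized so the 100 bins sum to 1, giving the BCI.
Smoothing is the centered 5-bin mean; edge bins use the truncated window,
which keeps smoothed values inside the convex hull of the input. Bin 1 sits
at the 3′ end by default (coverage profiles are conventionally displayed by
distance from the 3′ end); the orientation is configurable. Outlier genes
can be excluded by explicit id or by a reads-total > k·median rule (k = 50).

## Antisense discovery

The island caller is a transparent window/gap merger, not a reimplementation
of a peak caller with a Poisson background model: the genome is tiled with
fixed windows from coordinate 0, a read belongs to the window containing its
5′ end, windows with ≥ `min_window_reads` reads are eligible, and eligible
windows merge while the ineligible stretch between them is strictly smaller
than the gap. Round 1 uses 1000/3000 bp (window/gap), round 2 200/600 bp;
round-1 islands exactly one window long that contain a round-2 island
shorter than 401 bp are artifacts of single loaded windows and are dropped.

`min_window_reads` defaults to 1. Under uniform background this is too
permissive, so `min_reads_for_background(rate, window, alpha=0.01)` exposes
the Poisson-calibrated threshold (smallest k with
`P(Poisson(rate·window) ≥ k) < alpha`); the recovery tests use it at their
stated background rate.

Classification: an island is an unannotated antisense transcript when no
known gene on the same strand touches it (zero-overlap tolerance, the
strictest reading) and annotated genes on the opposite strand cover ≥ 20% of
its length; calls covered > 80% are dropped downstream. Known antisense
status comes from annotated features with biotype `antisense` (overridable).
Pooled multi-cell reads are deduplicated by (position, strand, length)
before calling. Antisense expression uses sense-strand unique reads, RPKM
normalization, and the ≥ 10 reads / RPKM > 0.1 expressed filter.

## Small-RNA cascade

The cascade classifies 50-nt reads in stages: (1) snoRNA by end-to-end
alignment with ≤ 1 mismatch; (2) a genome screen — genome-mapped reads leave
the small-RNA pool (an external flag or a naive exact screen; production
aligners are out of scope, the contract is aligner-agnostic); (3) miRNA:
reads trimmed to their 5′ 30 nt, aligned locally against pre-miRNA
references (16-nt seed), kept when the longest continuous perfect match is
17–25 nt and ≥ 80% of the matched run lies on a mature region (the overlap
fraction is a package choice, configurable); (4) tsRNA in two rounds against
tRNA references (40 nt/seed 30, then 30 nt/seed 18). Trimming always keeps
the 5′ prefix. The local aligner reports the best exact run (ties: leftmost
reference position, then lexicographic reference id); "local alignment with
one mismatch allowed" reduces to exact runs because the match-length filter
is defined on continuous perfect matches.

Exclusive mode (default for simulations) assigns each read at the earliest
accepting stage, so planted truth comparisons are exact; non-exclusive mode
reproduces the literal protocol in which miRNA and tsRNA counts draw from
the same genome-unmapped pool, and records every call per read. RPM uses the
per-library total of class-assigned reads as denominator by default
(configurable to total sequenced reads); reads are not deduplicated before
counting.

## Variability and bursting

The Fano factor is sample variance (n−1) over mean — the n−1 choice is the
package's convention where the source is silent. Bursting genes are selected
by: mRNA and intron RPKM > 0.1 in ≥ 5 cells; sense exon reads > 5 and sense
intron reads > 1 in ≥ 5 cells; intron length > 1000 bp (all strict). The
"5 of 10 cells" thresholds scale as ⌈n/2⌉ for other cell counts.

Top-variant selection transforms to `log2(x+1)`, computes per-feature mean
`u` and sd `s` (n−1), excludes `u < 1` and constant features, and ranks by
`V = u/s²` ascending — note `V` is an inverse dispersion index, so small
values mark the most variable features relative to their mean. Ties break by
feature id; a must-include list supports manual curation.

## Network inference

Candidate edges are validated catalog pairs. Detection requires a feature to
be nonzero in ≥ ⌈n/3⌉ of the scope cells (for 32 cells: nonzero in ≥ 11,
i.e. zero in at most 21; for 14 cells: ≥ 5), or, in the small-cell-set
variant, ≥ 1 read in ≥ 2 cells. Edges are retained when Spearman rho < 0
with two-sided p < 0.05. No multiple-testing correction is applied anywhere
in the cascade — that is the procedure being implemented; a
Benjamini–Hochberg option exists but is off by default.

Spearman uses average ranks; the primary p-value is the t-approximation
(`t = rho·√((n−2)/(1−rho²))`), and for n ≤ 9 an exact permutation p is
computed alongside because the approximation is coarse at the 7-cell scale.
The t tests come in the two study variants: Welch statistic with a
one-tailed p (taken in the direction of the observed difference, since the
tail direction is otherwise unspecified — a documented caveat) for the
oncomiR module's differential-expression stage, and pooled-variance
two-tailed for group comparisons. Correlations take raw RPKM/RPM input;
Spearman is rank-invariant, so log-transforming first would not change
anything.

The oncomiR module restricts the catalog to named oncomiRs, applies
detection over all cells, the negative-correlation filter, then requires
both members DE between subpopulation I and II∪III (Welch one-tailed,
p < 0.05). The suppressor module removes oncomiR interactions and applies
detection and correlation within the subpopulation II∪III subset only.

## Super-enhancers

Association anchors each feature at its transcription start (5′ end of the
gene interval, strand-aware) — TSS proximity is how the SE literature
assigns targets — and picks the minimum-distance gene and miRNA whose anchor
lies within ±100 kb of the SE interval (distance 0 inside; ties to the
smaller start coordinate). miRNAs within 10 kb of each other form
single-linkage clusters sharing one association. A manual override table
supports curated pairs.

Group expression z-scores each member feature across cells (on the
`log2(x+1)` scale, sample sd; zero-variance members dropped) and takes the
per-cell median; group activity min–max scales it to [0, 1], so the least
and most active cells sit at exactly 0 and 1. A constant group maps to 0.5
with a warning. Activity is invariant to positive affine transforms of group
expression.

## Clustering and embedding

Cells are clustered on their scaled feature profiles (euclidean metric;
complete linkage for the small-RNA/HCC-style analyses, average linkage
for the mRNA-library analysis — a per-profile configuration). Scaling
transforms are row-wise and composable: row-max division, z-score (sample
sd; zero-variance rows dropped with a warning), `log2(x+1)`. PCA keeps the
smallest set of top components whose eigenvalues reach 85% of the total;
t-SNE (over scikit-learn) embeds the scores with perplexity 6 (3 for the
antisense analysis), requiring `n_cells > 3·perplexity`. The embedding
contract is neighbor-structure only — coordinates are seed-deterministic but
otherwise arbitrary.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (configuration, seed) with a single
`numpy` Generator per call; emitted read counts equal the requested depth
exactly, and every truth record resolves to emitted data.

**Alignment libraries.** Reads (50 nt) are placed along merged exons; the
gene is drawn proportional to exon length and the start position follows a
named bias profile over the transcript coordinate `t ∈ [0,1]`: uniform;
5′-biased `exp(−4t)`; 3′-biased `exp(−4(1−t))`; central dropout
`0.05 + 0.95·(2t−1)²` for transcripts over 10 kb (a qualitative U-shape —
the bias contrasts in the source are described qualitatively only). Reads
truncate at the transcript end, so per-bp coverage has a structural ramp
within one read length of the gene ends; tests of exact per-bin flatness use
1-bp reads to remove that confound. Carrier reads live on their own contig
and never overlap the genome.

**Barcoded libraries.** Each template at each position draws one barcode
uniformly, doubles per cycle, and reads are sampled from the amplified pool
by multivariate hypergeometric draws. Truth records molecule counts and the
per-molecule barcode lineage, so collision-free positions can be checked
exactly.

**Small-RNA pools.** Reads are 50 nt: snoRNA reads are exact 50-nt
subsequences (so they survive an end-to-end screen); miRNA reads copy
17–25 nt of a mature region; tsRNA reads copy 28–40 nt 5′ or 3′ tRNA halves;
shorter inserts are 3′-filled with adapter. The first adapter base is forced
to differ from the reference continuation, so a perfect match can never
extend past the insert — without this, a 25-nt mature insert could extend to
a 26-nt run by chance and fail the 17–25 filter, breaking the exact-truth
contract on error-free pools. Sequencing error is a per-base substitution
rate; quality strings and adapter-ligation realism are not modeled.

**Dual transcriptomes.** Expression is log-normal with Poisson sampling:
per-feature baselines (genes log2-uniform 3–8, miRNAs 4–7), per-cell size
factors (sd 0.2 log2 units), Gaussian biological noise (sd 0.5), and counts
`Poisson(2^logexpr)`. This is the minimal model under which RPKM/RPM
detection thresholds and rank-correlation filters behave as on real
libraries. Three planted structures: (1) subpopulations — 32 cells in
groups of 11/11/10, with 120 marker genes and 15 marker miRNAs per group
shifted by +1.5 log2 units in their group; the markers span most of the
feature space because in a clustered tumor dataset the top-variant features
are themselves predominantly subpopulation-differential; (2) repression —
8 edges with target log2-expression = baseline − β·(centered miRNA
log2-expression) + noise (sd 0.3), β = 2 by default; (3) SE blocks — six
blocks of 8 genes + 1 miRNA sharing a latent per-cell activity with
distinct per-subpopulation means (±2) and noise sd 0.3. What passing tests
show is that the statistical machinery recovers planted structure at these
effect sizes; they do not certify performance on real libraries with
dropout, doublets, batch effects, or ambient contamination, none of which
are modeled.

**Antisense datasets.** The default scenario places single-exon + strand
genes (2 kb every 10 kb) each with one 2-kb planted antisense unit on the −
strand overlapping the gene's 3′ half. The ~50% overlap is deliberate: a
fully gene-contained antisense unit would be removed by the > 80%
opposite-cover filter, and a barely-overlapping one would fail the ≥ 20%
rule. Background reads are uniform per strand at a configurable per-bp rate.

## Problem sizes and numerical conventions

The test suite and examples run at desk scale, chosen as the smallest sizes
at which the statistical claims are sharp: dual transcriptomes of 32 cells ×
~560 features; alignment libraries of 5–30 k reads; small-RNA pools of
200–10,000 reads; 20-seed replication for recovery claims; 10⁶ Monte-Carlo
trials for the collision cross-check; 2,000 null pairs for the
correlation-filter calibration. Matrix round-trips hold to 12 significant
digits; oracle equivalences (island caller vs window scan, Spearman vs
rank-then-Pearson, clustering vs the O(n³) agglomerative oracle, BCI vs
per-bp accumulation) hold to 1e-9 relative or better. Ties in clustering
follow scipy's merge order; random test data makes exact ties
probability-zero.

## Known limitations

- The island caller approximates peak calling without an enrichment model;
  the eligibility threshold must be set against the background rate (a
  helper computes the Poisson-calibrated value).
- The naive aligner is exact-match/≤1-mismatch only and quadratic in the
  worst case; it is a contract implementation for the cascade, not a read
  mapper.
- One-tailed t-test direction follows the observed difference; with
  pre-specified directions, supply groups in the hypothesized order and
  interpret accordingly.
- `V = u/s²` ranks constant and near-constant features as undefined or
  extreme; features with `u < 1` are excluded before ranking, which also
  removes features whose variability is pure detection noise.
- t-SNE coordinates are not comparable across runs with different seeds;
  only neighbor structure is contracted.
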