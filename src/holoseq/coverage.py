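"""Gene-body coverage profiling: bin coverage indicators (BCI) per
transcript-length group with 5-bin moving-average smoothing.

Each gene's merged exons are divided into 100 near-equal bins; per-bp
coverage is normalized by the gene's exonic read total, summed per bin and
divided by bin length.  Genes are grouped by total exon length and the
group profile is normalized to sum to 1, giving the BCI; each BCI is then
smoothed by the centered 5-bin mean

    smoothed_BCI(n) = mean(BCI_{n-2} .. BCI_{n+2})

with truncated windows at the edges.  Bin 1 sits at the 3' end by default
(profiles are conventionally displayed by distance from the 3' end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from holoseq.io import AlignmentRecord, GeneModel, GenomicInterval

N_BINS = 100

# half-open [lo, hi) length groups in bp; "6kb-up" and "12kb-up" overlap by
# design: they are independent reporting groups
DEFAULT_GROUPS = {
    "0-2kb": (0, 2_000),
    "2-4kb": (2_000, 4_000),
    "4-6kb": (4_000, 6_000),
    "6kb-up": (6_000, float("inf")),
    "10-12kb": (10_000, 12_000),
    "12kb-up": (12_000, float("inf")),
}


@dataclass
class BCIProfile:
    group_label: str
    bci: np.ndarray
    smoothed_bci: np.ndarray
    n_genes: int


def _bin_edges(total_len: int, n_bins: int = N_BINS) -> np.ndarray:
    """Largest-remainder bin boundaries: bins differ by <= 1 bp, the
    remainder is spread over the last r bins."""
    base = total_len // n_bins
    r = total_len % n_bins
    widths = np.full(n_bins, base, dtype=int)
    if r:
        widths[-r:] += 1
    return np.concatenate([[0], np.cumsum(widths)])


def _exonic_coverage(gene: GeneModel, alignments: Iterable[AlignmentRecord]) -> tuple[np.ndarray, int]:
    """Per-bp coverage along the merged exons in 5'->3' transcript order,
    plus the exonic read count."""
    L = gene.exon_length
    cov = np.zeros(L, dtype=float)
    # map genomic coordinate -> transcript offset per exon
    offsets = []
    acc = 0
    for e in gene.exons:
        offsets.append((e.start, e.end, acc))
        acc += len(e)
    n_reads = 0
    for rec in alignments:
        if rec.interval.chrom != gene.chrom:
            continue
        hit = False
        for b in rec.blocks:
            for (es, ee, off) in offsets:
                lo = max(b.start, es)
                hi = min(b.end, ee)
                if lo < hi:
                    cov[off + lo - es : off + hi - es] += 1
                    hit = True
        n_reads += hit
    if gene.strand == "-":
        cov = cov[::-1]  # transcript 5'->3' runs right to left on the genome
    return cov, n_reads


def gene_bin_coverage(
    gene: GeneModel,
    alignments: Iterable[AlignmentRecord],
    from_end: str = "3p",
) -> np.ndarray:
    """Length-normalized coverage in 100 bins along the merged exons.

    Per-bp coverage is divided by the exon total read count, summed per bin
    and divided by the bin length.  Returns an all-zero vector when the gene
    has no exonic reads.  ``from_end="3p"`` numbers bin 1 from the 3' end.
    """
    cov, n_reads = _exonic_coverage(gene, alignments)
    if n_reads == 0:
        return np.zeros(N_BINS)
    norm = cov / n_reads
    edges = _bin_edges(gene.exon_length)
    vals = np.zeros(N_BINS)
    for i in range(N_BINS):
        lo, hi = edges[i], edges[i + 1]
        if hi > lo:
            vals[i] = norm[lo:hi].sum() / (hi - lo)
    if from_end == "3p":
        vals = vals[::-1]
    elif from_end != "5p":
        raise ValueError(f"unknown orientation {from_end!r}")
    return vals


def aggregate_group_bci(
    per_gene_bins: dict[str, np.ndarray],
    gene_lengths: dict[str, int],
    groups: Optional[dict[str, tuple[float, float]]] = None,
) -> dict[str, BCIProfile]:
    """Aggregate per-gene bin profiles into group BCI profiles.

    Per-bin values are summed across the genes of a length group and the
    100-bin vector is normalized to sum to 1.  Empty groups yield an
    all-NaN profile with n_genes = 0.
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    out = {}
    for label, (lo, hi) in groups.items():
        members = [g for g, L in gene_lengths.items() if lo <= L < hi and g in per_gene_bins]
        if not members:
            nan = np.full(N_BINS, np.nan)
            out[label] = BCIProfile(label, nan, nan.copy(), 0)
            continue
        total = np.zeros(N_BINS)
        for g in members:
            total += per_gene_bins[g]
        s = total.sum()
        bci = total / s if s > 0 else total
        out[label] = BCIProfile(label, bci, smooth_bci(bci), len(members))
    return out


def smooth_bci(bci: Sequence[float]) -> np.ndarray:
    """Centered 5-bin moving average; edge bins use the truncated window."""
    arr = np.asarray(bci, dtype=float)
    if arr.shape != (N_BINS,):
        raise ValueError(f"expected a length-{N_BINS} vector, got {arr.shape}")
    out = np.empty(N_BINS)
    for n in range(N_BINS):
        lo = max(0, n - 2)
        hi = min(N_BINS, n + 3)
        out[n] = arr[lo:hi].mean()
    return out


def exclude_outlier_genes(
    per_gene_totals: dict[str, float],
    exclude_ids: Optional[Iterable[str]] = None,
    k: float = 50.0,
) -> tuple[set, list[tuple[str, str]]]:
    """Drop genes by explicit id list or by a reads-total > k*median rule.

    Returns (kept gene ids, [(excluded id, reason), ...]).
    """
    log: list[tuple[str, str]] = []
    kept = set(per_gene_totals)
    if exclude_ids is not None:
        for gid in exclude_ids:
            if gid in kept:
                kept.discard(gid)
                log.append((gid, "explicit exclusion"))
    else:
        totals = np.array(list(per_gene_totals.values()), dtype=float)
        med = float(np.median(totals)) if len(totals) else 0.0
        if med > 0:
            for gid, t in per_gene_totals.items():
                if t > k * med:
                    kept.discard(gid)
                    log.append((gid, f"reads total {t:g} > {k:g} x median {med:g}"))
    return kept, log
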