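"""De novo antisense-transcript identification from stranded reads.

The caller is a transparent two-round window/gap island merger: the genome
is tiled with fixed windows from coordinate 0, windows holding at least
``min_window_reads`` reads (each read assigned to the window containing its
5' end) are eligible, and eligible windows separated by at most ``gap_bp``
of ineligible windows merge into one island.  Round 1 uses a big window
(1000 bp) and gap (3000 bp); round 2 a small window (200 bp) and gap
(600 bp).  Round-1 islands exactly one window long whose footprint contains
a round-2 island shorter than 401 bp are discarded (singleton-window
artifacts).  Surviving islands become unannotated antisense transcripts
when no same-strand gene touches them and annotated genes on the opposite
strand cover at least 20% of their length; islands more than 80% covered by
opposite-strand genes are dropped downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from holoseq.io import (
    AlignmentRecord,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    merge_intervals,
)
from holoseq.quant import normalize, select_expressed_reads_and_rpkm


@dataclass(frozen=True)
class Island:
    interval: GenomicInterval
    read_count: int
    round: int = 1


@dataclass(frozen=True)
class AntisenseTranscript:
    interval: GenomicInterval
    status: str  # known | unannotated
    same_strand_covered: bool
    opposite_overlap_fraction: float
    opposite_cover_fraction: float


def call_islands(
    reads: Iterable[AlignmentRecord],
    window_bp: int,
    gap_bp: int,
    min_window_reads: int = 1,
    round_label: int = 1,
) -> list[Island]:
    """Window/gap island calling on single-strand reads.

    Reads may span several chroms but must share one strand; islands never
    overlap within a strand.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    window_counts: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    strands = set()
    for rec in reads:
        strands.add(rec.strand)
        if len(strands) > 1:
            raise ValueError("call_islands expects reads of a single strand")
        w = rec.five_prime // window_bp
        window_counts[(rec.interval.chrom, rec.strand)][w] += 1
    islands: list[Island] = []
    for (chrom, strand), counts in sorted(window_counts.items()):
        eligible = sorted(w for w, n in counts.items() if n >= min_window_reads)
        if not eligible:
            continue
        start_w = prev_w = eligible[0]
        total = counts[start_w]
        for w in eligible[1:]:
            # merge while the ineligible stretch is strictly below the gap
            if (w - prev_w - 1) * window_bp < gap_bp:
                total += counts[w]
                prev_w = w
            else:
                islands.append(
                    Island(
                        GenomicInterval(chrom, start_w * window_bp, (prev_w + 1) * window_bp, strand),
                        total,
                        round_label,
                    )
                )
                start_w = prev_w = w
                total = counts[w]
        islands.append(
            Island(
                GenomicInterval(chrom, start_w * window_bp, (prev_w + 1) * window_bp, strand),
                total,
                round_label,
            )
        )
    return islands


def min_reads_for_background(
    background_rate: float, window_bp: int, alpha: float = 0.01
) -> int:
    """Smallest per-window read count k with P(Poisson(rate*window) >= k) <
    alpha — an eligibility threshold commensurate with uniform background."""
    if background_rate <= 0:
        return 1
    lam = background_rate * window_bp
    k = 1
    while poisson.sf(k - 1, lam) >= alpha:
        k += 1
    return k


def two_round_filter(
    round1: Sequence[Island],
    round2: Sequence[Island],
    round1_window: int = 1000,
    min_inner: int = 401,
) -> list[Island]:
    """Drop round-1 islands exactly one window long that contain a round-2
    island shorter than ``min_inner`` bp; keep everything else."""
    kept = []
    for isl in round1:
        if len(isl.interval) == round1_window:
            contains_small = any(
                r2.interval.chrom == isl.interval.chrom
                and r2.interval.strand == isl.interval.strand
                and r2.interval.start >= isl.interval.start
                and r2.interval.end <= isl.interval.end
                and len(r2.interval) < min_inner
                for r2 in round2
            )
            if contains_small:
                continue
        kept.append(isl)
    return kept


def _coverage_fraction(
    island: GenomicInterval, genes: Sequence[GeneModel], strand: str
) -> float:
    """Fraction of the island covered by the union of gene intervals on the
    given strand."""
    ivs = [
        GenomicInterval(island.chrom, max(island.start, g.interval.start),
                        min(island.end, g.interval.end), strand)
        for g in genes
        if g.strand == strand
        and g.chrom == island.chrom
        and g.interval.start < island.end
        and g.interval.end > island.start
    ]
    if not ivs:
        return 0.0
    covered = sum(len(iv) for iv in merge_intervals(ivs))
    return covered / len(island)


def classify_antisense(
    islands: Sequence[Island],
    genes: Sequence[GeneModel],
    known_antisense: Optional[set] = None,
    min_opposite_overlap: float = 0.20,
    max_opposite_cover: float = 0.80,
    apply_cover_filter: bool = True,
) -> list[AntisenseTranscript]:
    """Classify islands as known / unannotated antisense transcripts.

    ``known_antisense`` defaults to the ids of annotated genes with biotype
    "antisense"; islands overlapping those on the same strand are "known".
    Any other same-strand gene overlap (>= 1 bp) disqualifies the island.
    Unannotated calls require opposite-strand genes to cover at least
    ``min_opposite_overlap`` of the island; calls of either status covered
    more than ``max_opposite_cover`` are dropped when
    ``apply_cover_filter`` is set.
    """
    if known_antisense is None:
        known_antisense = {g.gene_id for g in genes if g.biotype == "antisense"}
    out: list[AntisenseTranscript] = []
    for isl in islands:
        iv = isl.interval
        opp_strand = "-" if iv.strand == "+" else "+"
        same = [
            g
            for g in genes
            if g.strand == iv.strand
            and g.chrom == iv.chrom
            and iv.overlap(g.interval) > 0
        ]
        same_known = [g for g in same if g.gene_id in known_antisense]
        same_other = [g for g in same if g.gene_id not in known_antisense]
        opposite_normal = [g for g in genes if g.gene_id not in known_antisense]
        frac = _coverage_fraction(iv, opposite_normal, opp_strand)
        if same_other:
            continue  # covered by a known gene on the same strand
        if same_known:
            status = "known"
        elif frac >= min_opposite_overlap:
            status = "unannotated"
        else:
            continue
        if apply_cover_filter and frac > max_opposite_cover:
            continue
        out.append(
            AntisenseTranscript(
                interval=iv,
                status=status,
                same_strand_covered=False,
                opposite_overlap_fraction=frac,
                opposite_cover_fraction=frac,
            )
        )
    return out


def dedup_pooled_reads(reads: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Pool reads from all cells and drop redundant ones, keyed by
    (chrom, position, strand, length)."""
    seen = set()
    out = []
    for rec in reads:
        key = (rec.interval.chrom, rec.interval.start, rec.strand, len(rec.interval))
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def discover_antisense(
    reads: Sequence[AlignmentRecord],
    genes: Sequence[GeneModel],
    round1: tuple[int, int] = (1000, 3000),
    round2: tuple[int, int] = (200, 600),
    min_window_reads: int = 1,
    min_window_reads_round2: Optional[int] = None,
    known_antisense: Optional[set] = None,
    dedup: bool = True,
) -> list[AntisenseTranscript]:
    """Full antisense discovery: per-strand two-round island calling, the
    singleton-window filter, and annotation-overlap classification."""
    if dedup:
        reads = dedup_pooled_reads(reads)
    if min_window_reads_round2 is None:
        min_window_reads_round2 = min_window_reads
    results: list[AntisenseTranscript] = []
    for strand in ("+", "-"):
        sreads = [r for r in reads if r.strand == strand]
        if not sreads:
            continue
        r1 = call_islands(sreads, round1[0], round1[1], min_window_reads, round_label=1)
        r2 = call_islands(sreads, round2[0], round2[1], min_window_reads_round2, round_label=2)
        kept = two_round_filter(r1, r2, round1_window=round1[0])
        results.extend(classify_antisense(kept, genes, known_antisense))
    return results


def antisense_expression(
    transcripts: Sequence[AntisenseTranscript],
    alignments_per_cell: dict[str, Sequence[AlignmentRecord]],
    min_reads: int = 10,
    rpkm_threshold: float = 0.1,
) -> ExpressionMatrix:
    """Strand-specific RPKM matrix over antisense transcripts.

    Counts unique-mapped sense-strand reads per transcript per cell,
    normalizes by transcript length and per-cell mapped totals, and keeps
    transcripts with >= ``min_reads`` in >= 1 library and RPKM strictly >
    ``rpkm_threshold`` in >= 1 library.
    """
    names = [
        f"AS_{t.interval.chrom}:{t.interval.start}-{t.interval.end}({t.interval.strand})"
        for t in transcripts
    ]
    cells = list(alignments_per_cell)
    counts = pd.DataFrame(0, index=names, columns=cells, dtype=int)
    totals = {}
    for cell, recs in alignments_per_cell.items():
        recs = [r for r in recs if r.is_unique]
        totals[cell] = len(recs)
        for t, name in zip(transcripts, names):
            iv = t.interval
            n = sum(
                1
                for r in recs
                if r.strand == iv.strand and r.interval.overlap(iv) > 0
            )
            counts.loc[name, cell] = n
    lengths = pd.Series(
        [len(t.interval) for t in transcripts], index=names, dtype=int
    )
    rpkm = pd.DataFrame(0.0, index=names, columns=cells)
    for cell in cells:
        if totals[cell] > 0:
            rpkm[cell] = [
                normalize(c, L, totals[cell], "RPKM")
                for c, L in zip(counts[cell], lengths)
            ]
    keep = select_expressed_reads_and_rpkm(counts, rpkm, min_reads, rpkm_threshold, 1)
    return ExpressionMatrix(
        rpkm.loc[keep],
        pd.Series("antisense", index=keep),
        lengths.loc[keep],
    )
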