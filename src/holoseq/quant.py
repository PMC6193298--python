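"""Read counting, RPKM/RPM normalization, expressed-feature filters, carrier
accounting, and the degenerate-barcode deduplication model.

The barcode model follows the library-amplification design in which the
first PCR cycles use primers carrying an 8-nt degenerate barcode (4^8 =
65,536 barcodes).  Counting distinct barcodes per mapped position removes
PCR duplicates; the per-position collision probability is the classic
birthday product.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from holoseq.io import AlignmentRecord, GeneModel, GenomicInterval


@dataclass
class CountTable:
    """Per-feature read counts plus library totals."""

    counts: dict = field(default_factory=dict)  # feature_id -> dict of count kinds
    library_total_mapped: int = 0
    library_total_exome_mapped: int = 0


@dataclass
class BarcodeModel:
    """Degenerate-barcode amplification model.

    n_barcodes: size of the barcode space (default 4^8 = 65,536).
    max_reads_per_position: templates per unique position before
        amplification (observed ceiling ~10 in 2M-read exome libraries).
    cycles: barcoded amplification cycles (each doubles every fragment).
    """

    n_barcodes: int = 4**8
    max_reads_per_position: int = 10
    cycles: int = 10

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")


# ---------------------------------------------------------------------------
# counting


def _blocks_overlap_any(
    blocks: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> bool:
    for b in blocks:
        for r in regions:
            if b.overlap(r) > 0:
                return True
    return False


def count_reads(
    alignments: Iterable[AlignmentRecord],
    gene: GeneModel,
    region: str = "exon",
    strand_mode: str = "sense",
) -> int:
    """Count unique-mapped reads overlapping a gene region by >= 1 bp.

    A read counts once per gene if any aligned block overlaps the region on
    the required strand.  A read overlapping both exon and intron counts to
    the exon only (exon precedence).
    """
    if region not in ("exon", "intron"):
        raise ValueError(f"unknown region {region!r}")
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    exons = gene.exons
    introns = gene.introns
    n = 0
    for rec in alignments:
        if not rec.is_unique:
            continue
        if rec.interval.chrom != gene.chrom:
            continue
        if strand_mode == "sense" and rec.strand != gene.strand:
            continue
        in_exon = _blocks_overlap_any(rec.blocks, exons)
        if region == "exon":
            n += in_exon
        else:
            if not in_exon and _blocks_overlap_any(rec.blocks, introns):
                n += 1
    return n


def normalize(
    count: float, feature_length_bp: int, library_total_mapped: int, kind: str = "RPKM"
) -> float:
    """RPKM = count/(L/1e3)/(T/1e6); RPM = count/(T/1e6)."""
    if library_total_mapped <= 0:
        raise ValueError("library total must be > 0")
    if kind == "RPKM":
        if feature_length_bp <= 0:
            raise ValueError("feature length must be > 0 for RPKM")
        return count / (feature_length_bp / 1e3) / (library_total_mapped / 1e6)
    if kind == "RPM":
        return count / (library_total_mapped / 1e6)
    raise ValueError(f"unknown normalization kind {kind!r}")


# ---------------------------------------------------------------------------
# expressed-feature filters


def select_expressed_avg(rpkm: pd.DataFrame, threshold: float = 0.1) -> list[str]:
    """Features whose mean RPKM across libraries is strictly > threshold."""
    means = rpkm.mean(axis=1)
    return list(means.index[means > threshold])


def select_expressed_reads_and_rpkm(
    counts: pd.DataFrame,
    rpkm: pd.DataFrame,
    min_reads: int = 10,
    rpkm_threshold: float = 0.1,
    k_libraries: int = 1,
) -> list[str]:
    """Features with >= min_reads in >= k libraries AND RPKM strictly >
    rpkm_threshold in >= k libraries.

    Matches the "at least 10 reads mapped in at least one library and ...
    strand-specific RPKM larger than 0.1 in at least one library" rule:
    "at least" is >=, "larger than" is strict >.
    """
    ok_reads = (counts >= min_reads).sum(axis=1) >= k_libraries
    ok_rpkm = (rpkm > rpkm_threshold).sum(axis=1) >= k_libraries
    keep = ok_reads & ok_rpkm.reindex(ok_reads.index, fill_value=False)
    return list(keep.index[keep])


# ---------------------------------------------------------------------------
# carrier accounting


def partition_carrier(
    alignments: Iterable[AlignmentRecord],
    is_carrier: Optional[Callable[[AlignmentRecord], bool]] = None,
    true_carrier_ids: Optional[set] = None,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], float]:
    """Split reads into (cellular, carrier) and report removal efficiency.

    By default a read is carrier when ``source_ref == "carrier"``.  If
    ``true_carrier_ids`` is given, efficiency = detected true carrier reads /
    true carrier reads; otherwise every detected carrier read is its own
    truth and efficiency is 1.0 (vacuously 1.0 with zero carrier reads).
    """
    if is_carrier is None:
        is_carrier = lambda rec: rec.source_ref == "carrier"
    cellular: list[AlignmentRecord] = []
    carrier: list[AlignmentRecord] = []
    for rec in alignments:
        (carrier if is_carrier(rec) else cellular).append(rec)
    if true_carrier_ids is not None:
        n_true = len(true_carrier_ids)
        if n_true == 0:
            return cellular, carrier, 1.0
        n_hit = sum(1 for rec in carrier if rec.read_id in true_carrier_ids)
        return cellular, carrier, n_hit / n_true
    return cellular, carrier, 1.0


def count_restriction_sites(sequence: str, motif: str = "GCGGCCGC") -> list[int]:
    """All exact motif start positions, overlapping occurrences included."""
    positions = []
    start = sequence.find(motif)
    while start != -1:
        positions.append(start)
        start = sequence.find(motif, start + 1)
    return positions


# ---------------------------------------------------------------------------
# barcoded deduplication


def _position_key(rec: AlignmentRecord) -> tuple[str, int, str]:
    # fragment identity = (chrom, 5'-most aligned coordinate, strand)
    return (rec.interval.chrom, rec.five_prime, rec.strand)


def dedup_barcoded(
    alignments: Iterable[AlignmentRecord],
) -> tuple[dict[tuple[str, int, str], int], int]:
    """Unique-barcode counts per mapped position.

    Returns ({position: distinct barcode count}, n_reads_without_barcode).
    Position = (chrom, 5'-most aligned coordinate, strand).
    """
    barcodes: dict[tuple[str, int, str], set] = defaultdict(set)
    n_missing = 0
    for rec in alignments:
        if rec.barcode is None:
            n_missing += 1
            continue
        barcodes[_position_key(rec)].add(rec.barcode)
    return {k: len(v) for k, v in barcodes.items()}, n_missing


def barcoded_gene_counts(
    alignments: Sequence[AlignmentRecord], genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Gene-level barcoded counts: sum of per-position unique-barcode counts
    over positions whose 5' coordinate falls in the gene's exons."""
    position_counts, _ = dedup_barcoded(alignments)
    out = {}
    for gene in genes:
        total = 0
        for (chrom, pos, strand), n in position_counts.items():
            if chrom != gene.chrom:
                continue
            if any(e.start <= pos < e.end for e in gene.exons):
                total += n
        out[gene.gene_id] = total
    return out


def barcode_collision_probability(n_reads: int, n_barcodes: int = 4**8) -> float:
    """Birthday-collision probability among n_reads independently and
    uniformly barcoded molecules at one position:

        P = 1 - prod_{i=1}^{n_reads-1} (1 - i/n_barcodes)

    Returns 1.0 when n_reads > n_barcodes (pigeonhole).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if n_reads > n_barcodes:
        return 1.0
    log_no_collision = 0.0
    for i in range(1, n_reads):
        log_no_collision += math.log1p(-i / n_barcodes)
    return -math.expm1(log_no_collision)


def max_distinct_barcoded_reads(model: BarcodeModel) -> int:
    """Ceiling on distinct barcoded fragments one position can yield:
    max_reads_per_position templates, each doubling once per barcoded cycle.
    """
    return model.max_reads_per_position * 2**model.cycles
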