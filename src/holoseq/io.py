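"""Core genomic types and readers/writers for the formats every stage touches.

All coordinates are 0-based half-open internally.  GTF input (1-based,
inclusive) is converted at the boundary; BED is passed through unchanged.
"""

from __future__ import annotations

import io as _io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

FEATURE_CLASSES = ("mRNA", "miRNA", "tsRNA", "snoRNA", "antisense")


class FormatError(ValueError):
    """Raised on malformed input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp, ignoring strand (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on one chrom/strand, sorted and disjoint."""
    if not intervals:
        return []
    chroms = {(iv.chrom, iv.strand) for iv in intervals}
    if len(chroms) > 1:
        raise ValueError("cannot merge intervals across chroms/strands")
    chrom, strand = next(iter(chroms))
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = [(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        s, e = merged[-1]
        if iv.start <= e:
            merged[-1] = (s, max(e, iv.end))
        else:
            merged.append((iv.start, iv.end))
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with merged exon blocks; introns are the gaps."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
        first, last = self.exons[0], self.exons[-1]
        if first.start < self.interval.start or last.end > self.interval.end:
            raise ValueError(f"gene {self.gene_id}: exons outside gene interval")
        if self.exon_length <= 0:
            raise ValueError(f"gene {self.gene_id}: zero exon length")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)

    @property
    def intron_length(self) -> int:
        return sum(len(i) for i in self.introns)


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read.

    ``blocks`` holds the aligned reference blocks (several for spliced
    alignments); ``interval`` spans the first to last block.  ``match_run``
    is the longest continuous perfect-match (M) run in nucleotides.
    """

    read_id: str
    interval: GenomicInterval
    is_unique: bool = True
    match_run: int = 0
    barcode: Optional[str] = None
    source_ref: str = "genome"
    blocks: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.barcode is not None and (
            len(self.barcode) != 8 or set(self.barcode) - set("ACGT")
        ):
            raise ValueError(f"read {self.read_id}: invalid barcode {self.barcode!r}")
        if not self.blocks:
            object.__setattr__(self, "blocks", (self.interval,))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        """5'-most aligned coordinate (start on +, end-1 on -)."""
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class ExpressionMatrix:
    """Features x cells expression values with per-feature annotations.

    ``values`` is a pandas DataFrame indexed by feature_id with cell_id
    columns.  ``feature_class`` and ``feature_length_bp`` are Series on the
    same index; length is required for RPKM features and may be 0 for RPM
    features (miRNA etc.).
    """

    values: pd.DataFrame
    feature_class: pd.Series = None
    feature_length_bp: pd.Series = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature_id {dup!r}")
        if self.feature_class is None:
            self.feature_class = pd.Series("mRNA", index=self.values.index)
        if self.feature_length_bp is None:
            self.feature_length_bp = pd.Series(0, index=self.values.index)
        self.feature_class = self.feature_class.reindex(self.values.index)
        self.feature_length_bp = self.feature_length_bp.reindex(
            self.values.index
        ).fillna(0).astype(int)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        feats = [f for f in features if f in self.values.index]
        return ExpressionMatrix(
            self.values.loc[feats].copy(),
            self.feature_class.loc[feats].copy(),
            self.feature_length_bp.loc[feats].copy(),
        )


# ---------------------------------------------------------------------------
# gene model readers


def _as_lines(stream: Union[str, TextIO]) -> Iterator[tuple[int, str]]:
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line


def _detect_dialect(lines: list[tuple[int, str]]) -> str:
    if not lines:
        return "bed12"
    fields = lines[0][1].split("\t")
    if len(fields) == 1:
        fields = lines[0][1].split()
    if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
        # GTF: columns 4/5 are coordinates and column 9 holds attributes
        if "gene_id" in lines[0][1] or fields[2] in ("exon", "gene", "transcript", "CDS"):
            return "gtf"
    return "bed12"


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(stream: Union[str, TextIO]) -> list[GeneModel]:
    """Parse gene models from BED12 or GTF text (dialect auto-detected).

    GTF exon records are collapsed per gene_id: the exon union over all
    transcripts forms the merged exon blocks.  Output is ordered by
    (chrom, start, gene_id).
    """
    lines = list(_as_lines(stream))
    dialect = _detect_dialect(lines)
    if dialect == "gtf":
        genes = _read_gtf(lines)
    else:
        genes = _read_bed12(lines)
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _read_bed12(lines: list[tuple[int, str]]) -> list[GeneModel]:
    by_gene: dict[str, list[GenomicInterval]] = {}
    biotypes: dict[str, str] = {}
    for lineno, line in lines:
        f = line.split("\t")
        if len(f) < 6:
            f = line.split()
        if len(f) < 6:
            raise FormatError(f"line {lineno}: expected >=6 BED columns")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            if len(f) >= 12:
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ValueError("block count mismatch")
                exons = [
                    GenomicInterval(chrom, start + o, start + o + s, strand)
                    for s, o in zip(sizes, offsets)
                ]
            else:
                exons = [GenomicInterval(chrom, start, end, strand)]
        except (ValueError, IndexError) as exc:
            raise FormatError(f"line {lineno}: malformed BED record ({exc})") from exc
        # name field may carry biotype as "id|biotype"
        if "|" in name:
            name, biotype = name.split("|", 1)
            biotypes[name] = biotype
        by_gene.setdefault(name, []).extend(exons)
    return _collapse(by_gene, biotypes)


def _read_gtf(lines: list[tuple[int, str]]) -> list[GeneModel]:
    by_gene: dict[str, list[GenomicInterval]] = {}
    biotypes: dict[str, str] = {}
    for lineno, line in lines:
        f = line.split("\t")
        if len(f) != 9:
            raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(f)}")
        if f[2] != "exon":
            continue
        try:
            start = int(f[3]) - 1  # GTF is 1-based inclusive
            end = int(f[4])
            iv = GenomicInterval(f[0], start, end, f[6])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed GTF record ({exc})") from exc
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gid = attrs.get("gene_id")
        if not gid:
            raise FormatError(f"line {lineno}: missing gene_id attribute")
        by_gene.setdefault(gid, []).append(iv)
        if "gene_biotype" in attrs:
            biotypes[gid] = attrs["gene_biotype"]
    return _collapse(by_gene, biotypes)


def _collapse(
    by_gene: dict[str, list[GenomicInterval]], biotypes: dict[str, str]
) -> list[GeneModel]:
    out = []
    for gid, ivs in by_gene.items():
        merged = merge_intervals(ivs)
        total = sum(len(e) for e in merged)
        if total == 0:
            raise FormatError(f"gene {gid}: zero exon length")
        span = GenomicInterval(
            merged[0].chrom, merged[0].start, merged[-1].end, merged[0].strand
        )
        out.append(
            GeneModel(gid, span, tuple(merged), biotypes.get(gid, "protein_coding"))
        )
    return out


# ---------------------------------------------------------------------------
# alignment readers

_SAM_FLAG_UNMAPPED = 0x4
_SAM_FLAG_REVERSE = 0x10
_SAM_FLAG_SECONDARY = 0x100

_CIGAR_RE = re.compile(r"(\d+)([MIDSN])")
_SUPPORTED_CIGAR = set("MIDSN")


@dataclass
class ReadStats:
    """Side counts accumulated while streaming alignments."""

    n_records: int = 0
    n_unmapped: int = 0
    n_bad_barcode: int = 0


def _parse_cigar(cigar: str, lineno: int) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        bad = re.sub(r"[\dMIDSN]", "", cigar) or cigar
        raise FormatError(f"line {lineno}: unsupported CIGAR op in {cigar!r} ({bad!r})")
    return [(int(n), o) for n, o in ops]


def _longest_m_run(ops: list[tuple[int, str]]) -> int:
    best = cur = 0
    for n, op in ops:
        if op == "M":
            cur += n
            best = max(best, cur)
        else:
            cur = 0
    return best


def _barcode_from_name(read_id: str) -> tuple[str, Optional[str]]:
    """Split a trailing '#BC<seq>' barcode field off the read name."""
    if "#BC" in read_id:
        base, bc = read_id.rsplit("#BC", 1)
        return base, bc
    return read_id, None


def read_alignments(
    stream: Union[str, TextIO],
    barcode_tag: str = "BC",
    stats: Optional[ReadStats] = None,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from SAM-subset or BED6 text.

    SAM records use the FLAG strand bit, POS and a CIGAR over M/I/D/S/N;
    barcodes come from the named tag (``<tag>:Z:``) or a trailing read-name
    field ``#BC``.  Unmapped records are skipped but counted in ``stats``.
    Barcodes of the wrong length are dropped with a warning (record kept).
    """
    if stats is None:
        stats = ReadStats()
    lines = list(_as_lines(stream))
    fmt = None
    for lineno, line in lines:
        if line.startswith("@"):
            continue
        f = line.split("\t")
        if fmt is None:
            fmt = "sam" if len(f) >= 11 else "bed"
        if fmt == "sam":
            rec = _parse_sam_line(f, lineno, barcode_tag, stats)
        else:
            rec = _parse_bed_line(f, lineno, stats)
        if rec is not None:
            yield rec


def _clean_barcode(
    read_id: str, bc: Optional[str], stats: ReadStats
) -> Optional[str]:
    if bc is None:
        return None
    if len(bc) != 8 or set(bc) - set("ACGT"):
        stats.n_bad_barcode += 1
        warnings.warn(f"read {read_id}: dropping malformed barcode {bc!r}")
        return None
    return bc


def _parse_sam_line(
    f: list[str], lineno: int, barcode_tag: str, stats: ReadStats
) -> Optional[AlignmentRecord]:
    stats.n_records += 1
    try:
        qname, flag, rname, pos, mapq = f[0], int(f[1]), f[2], int(f[3]), int(f[4])
        cigar = f[5]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: malformed SAM record ({exc})") from exc
    if flag & _SAM_FLAG_UNMAPPED:
        stats.n_unmapped += 1
        return None
    ops = _parse_cigar(cigar, lineno)
    strand = "-" if flag & _SAM_FLAG_REVERSE else "+"
    start = pos - 1  # SAM POS is 1-based
    blocks: list[GenomicInterval] = []
    ref = start
    block_start = start
    open_block = False
    for n, op in ops:
        if op in ("M", "D"):
            if not open_block:
                block_start = ref
                open_block = True
            ref += n
        elif op == "N":
            if open_block:
                blocks.append(GenomicInterval(rname, block_start, ref, strand))
                open_block = False
            ref += n
        # I and S consume no reference
    if open_block:
        blocks.append(GenomicInterval(rname, block_start, ref, strand))
    if not blocks:
        raise FormatError(f"line {lineno}: CIGAR {cigar!r} consumes no reference")
    interval = GenomicInterval(rname, blocks[0].start, blocks[-1].end, strand)
    bc = None
    for tag in f[11:]:
        if tag.startswith(f"{barcode_tag}:Z:"):
            bc = tag.split(":", 2)[2]
    qname, name_bc = _barcode_from_name(qname)
    if bc is None:
        bc = name_bc
    is_unique = mapq > 0 and not (flag & _SAM_FLAG_SECONDARY)
    return AlignmentRecord(
        read_id=qname,
        interval=interval,
        is_unique=is_unique,
        match_run=_longest_m_run(ops),
        barcode=_clean_barcode(qname, bc, stats),
        blocks=tuple(blocks),
    )


def _parse_bed_line(
    f: list[str], lineno: int, stats: ReadStats
) -> Optional[AlignmentRecord]:
    stats.n_records += 1
    if len(f) < 6:
        raise FormatError(f"line {lineno}: expected >=6 BED columns")
    try:
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: malformed BED record ({exc})") from exc
    read_id, bc = _barcode_from_name(f[3])
    return AlignmentRecord(
        read_id=read_id,
        interval=iv,
        is_unique=True,
        match_run=len(iv),
        barcode=_clean_barcode(read_id, bc, stats),
    )


# ---------------------------------------------------------------------------
# matrix I/O

_META_COLS = ["feature_class", "length_bp"]


def write_matrix(matrix: ExpressionMatrix, stream: TextIO) -> None:
    """Write a row-major TSV with feature annotations as leading columns.

    Values are printed with 12 significant digits so that
    ``read_matrix(write_matrix(m))`` reproduces them.
    """
    df = matrix.values
    header = ["feature_id"] + _META_COLS + list(df.columns)
    stream.write("\t".join(header) + "\n")
    classes = matrix.feature_class
    lengths = matrix.feature_length_bp
    arr = df.to_numpy()
    for i, fid in enumerate(df.index):
        vals = "\t".join(format(v, ".12g") for v in arr[i])
        row = f"{fid}\t{classes.iloc[i]}\t{lengths.iloc[i]}"
        stream.write(row + ("\t" + vals if len(df.columns) else "") + "\n")


def read_matrix(stream: Union[str, TextIO]) -> ExpressionMatrix:
    """Read a TSV written by :func:`write_matrix`."""
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    df = pd.read_csv(handle, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature_id {dup!r}")
    classes = df["feature_class"] if len(df) else pd.Series(dtype=str)
    lengths = df["length_bp"].astype(int) if len(df) else pd.Series(dtype=int)
    values = df.drop(columns=_META_COLS).astype(float)
    values.columns = [str(c) for c in values.columns]
    return ExpressionMatrix(values, classes, lengths)
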