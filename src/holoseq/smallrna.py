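"""Small-RNA classification cascade: snoRNA, miRNA, and tsRNA calls over an
abstract aligner contract, with RPM output.

The cascade mirrors a staged mapping strategy for 50-bp small-RNA reads:

1. snoRNA: end-to-end alignment of the raw read against snoRNA references
   with at most one mismatch.
2. Genome screen: reads that map to the genome leave the small-RNA pool;
   the later stages see only genome-unmapped reads.  Genome mapping is an
   external flag (or a naive exact screen against a toy genome) — the
   cascade is aligner-agnostic.
3. miRNA: reads trimmed to their first 30 nt, local (exact-run) alignment
   against pre-miRNA references with a 16-nt seed; calls require a
   17-25 nt continuous perfect match lying on a mature-miRNA region.
4. tsRNA: two rounds against tRNA references — first 40 nt with a 30-nt
   seed, then (for round-1 misses) first 30 nt with an 18-nt seed.

Trimming always keeps the 5' prefix.  In exclusive mode (default for
simulations) each read receives at most one call, assigned at the earliest
stage that accepts it; non-exclusive mode reproduces the literal protocol
in which the miRNA and tsRNA stages draw from the same genome-unmapped
pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from holoseq.io import ExpressionMatrix

MIRNA_MIN_RUN = 17
MIRNA_MAX_RUN = 25

_BASE_CODE = {c: i for i, c in enumerate("ACGTN#")}


def read_fasta(stream: Union[str, TextIO]) -> dict[str, str]:
    """Read a FASTA into an id -> sequence dict (first word of header)."""
    import io as _io

    from Bio.SeqIO.FastaIO import SimpleFastaParser

    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    return {
        title.split()[0]: seq.upper() for title, seq in SimpleFastaParser(handle)
    }


def read_mature_bed(stream: Union[str, TextIO]) -> dict[str, list[tuple[int, int]]]:
    """Read mature-miRNA intervals (0-based half-open, on the pre-miRNA
    reference) from BED-like text: ref_id, start, end[, name]."""
    import io as _io

    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    out: dict[str, list[tuple[int, int]]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) == 1:
            f = line.split()
        if len(f) < 3:
            raise ValueError(f"mature BED line {lineno}: expected >= 3 columns")
        out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


@dataclass
class SmallRNARefs:
    """Reference sequences for the cascade.

    ``mature`` maps each pre-miRNA id to its mature sub-intervals
    (0-based half-open on the pre-miRNA sequence).
    """

    snorna: dict[str, str] = field(default_factory=dict)
    pre_mirna: dict[str, str] = field(default_factory=dict)
    mature: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    trna: dict[str, str] = field(default_factory=dict)
    genome: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        for mid, ivs in self.mature.items():
            if mid not in self.pre_mirna:
                raise ValueError(
                    f"mature interval names unknown pre-miRNA {mid!r}"
                )
            L = len(self.pre_mirna[mid])
            for s, e in ivs:
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"mature interval [{s},{e}) outside pre-miRNA {mid!r}"
                    )
        for name, d in (
            ("snoRNA", self.snorna),
            ("pre-miRNA", self.pre_mirna),
            ("tRNA", self.trna),
        ):
            for rid, seq in d.items():
                if not seq:
                    raise ValueError(f"empty {name} reference {rid!r}")


@dataclass(frozen=True)
class NaiveAlignment:
    ref_id: str
    ref_pos: int  # start of the placement (end_to_end) or of the run (local)
    read_pos: int
    match_run: int
    mismatches: int


@dataclass(frozen=True)
class SmallRNACall:
    read_id: str
    assigned_class: str  # snoRNA | miRNA | tsRNA | unassigned
    reference_id: Optional[str]
    match_run: int
    stage: str


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class _RefIndex:
    """Concatenated references with '##' separators, for vectorized scans."""

    def __init__(self, refs: dict[str, str]):
        self.ids = sorted(refs)
        parts = []
        self.offsets: list[tuple[int, int, str]] = []  # (start, end, id)
        pos = 0
        for rid in self.ids:
            seq = refs[rid].upper()
            parts.append(seq)
            self.offsets.append((pos, pos + len(seq), rid))
            pos += len(seq) + 2
            parts.append("##")
        self.concat = _encode("".join(parts))

    def locate(self, j: int) -> tuple[str, int]:
        for s, e, rid in self.offsets:
            if s <= j < e:
                return rid, j - s
        raise ValueError("position in separator")


def _end_to_end_scan(
    read: str, index: _RefIndex, max_mismatch: int
) -> Optional[NaiveAlignment]:
    r = _encode(read.upper())
    n = len(r)
    C = index.concat
    if n > len(C):
        return None
    windows = np.lib.stride_tricks.sliding_window_view(C, n)
    mism = (windows != r).sum(axis=1)
    best: Optional[tuple[int, int, str, int]] = None  # (mm, ref_pos, ref_id, j)
    for j in np.flatnonzero(mism <= max_mismatch):
        rid, ref_pos = _locate_window(index, int(j), n)
        if rid is None:
            continue  # window crosses a reference boundary
        key = (int(mism[j]), ref_pos, rid, int(j))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mm, ref_pos, rid, j = best
    eq = windows[j] == r
    return NaiveAlignment(rid, ref_pos, 0, _longest_true_run(eq), mm)


def _locate_window(index: _RefIndex, j: int, n: int) -> tuple[Optional[str], int]:
    for s, e, rid in index.offsets:
        if s <= j and j + n <= e:
            return rid, j - s
    return None, -1


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _local_scan(read: str, index: _RefIndex, seed_len: int) -> Optional[NaiveAlignment]:
    """Longest common substring of read vs every reference, vectorized per
    read position; ties broken by leftmost reference position then
    lexicographic reference id."""
    r = _encode(read.upper())
    C = index.concat
    prev = np.zeros(len(C), dtype=np.int32)
    best_run = 0
    candidates: list[tuple[int, int, int]] = []  # (run, j_end, i_end)
    for i, c in enumerate(r):
        cur = np.zeros(len(C), dtype=np.int32)
        match = C == c
        cur[match] = 1
        shifted = np.empty(len(C), dtype=np.int32)
        shifted[0] = 0
        shifted[1:] = prev[:-1]
        cur[match] += shifted[match]
        m = int(cur.max()) if len(cur) else 0
        if m > best_run:
            best_run = m
            candidates = []
        if m == best_run and m > 0:
            for j in np.flatnonzero(cur == m):
                candidates.append((m, int(j), i))
        prev = cur
    if best_run < seed_len:
        return None
    scored = []
    for run, j_end, i_end in candidates:
        if run != best_run:
            continue
        rid, ref_end = index.locate(j_end)
        ref_pos = ref_end - run + 1
        scored.append((ref_pos, rid, i_end - run + 1))
    ref_pos, rid, read_pos = min(scored)
    return NaiveAlignment(rid, ref_pos, read_pos, best_run, 0)


def align_naive(
    read: str,
    reference: Union[str, dict[str, str]],
    mode: str = "end_to_end",
    seed_len: int = 16,
    max_mismatch: int = 1,
) -> Optional[NaiveAlignment]:
    """Best placement of ``read`` against one reference or a dict of them.

    ``end_to_end``: best full-read placement with <= max_mismatch
    mismatches, else None.  ``local``: best contiguous exact-match run of at
    least ``seed_len`` nt (the reported ``match_run``), else None.  Ties are
    broken by leftmost reference position, then lexicographic reference id.
    """
    refs = {"ref": reference} if isinstance(reference, str) else reference
    if not refs:
        return None
    index = _RefIndex(refs)
    if mode == "end_to_end":
        hit = _end_to_end_scan(read, index, max_mismatch)
    elif mode == "local":
        hit = _local_scan(read, index, seed_len)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if hit is not None and isinstance(reference, str):
        return NaiveAlignment("ref", hit.ref_pos, hit.read_pos, hit.match_run, hit.mismatches)
    return hit


def _mature_overlap_ok(
    hit: NaiveAlignment,
    mature: dict[str, list[tuple[int, int]]],
    min_frac: float,
) -> bool:
    ivs = mature.get(hit.ref_id, [])
    run_start, run_end = hit.ref_pos, hit.ref_pos + hit.match_run
    covered = sum(
        max(0, min(run_end, e) - max(run_start, s)) for s, e in ivs
    )
    return covered >= min_frac * hit.match_run


def classify_cascade(
    reads: Sequence[tuple[str, str]],
    refs: SmallRNARefs,
    exclusive: bool = True,
    genome_mapped: Optional[Callable[[str], bool]] = None,
    mature_overlap_frac: float = 0.8,
    max_read_len: int = 50,
) -> tuple[list[SmallRNACall], dict[str, int]]:
    """Run the snoRNA -> genome -> miRNA -> tsRNA cascade.

    ``reads`` are (read_id, sequence) pairs; sequences longer than 50 nt are
    truncated with a warning.  ``genome_mapped(read_id)`` flags reads that
    map to the genome and therefore leave the small-RNA pool after the
    snoRNA stage; with ``refs.genome`` set, a naive exact-substring screen
    is used instead.  Returns (calls, per-class counts); counts include
    "unassigned".
    """
    calls: dict[str, list[SmallRNACall]] = {}
    pool: list[tuple[str, str]] = []
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) > max_read_len:
            warnings.warn(f"read {rid}: truncating to {max_read_len} nt")
            seq = seq[:max_read_len]
        pool.append((rid, seq))

    def _assign(rid: str, cls: str, hit: NaiveAlignment, stage: str) -> None:
        calls.setdefault(rid, []).append(
            SmallRNACall(rid, cls, hit.ref_id, hit.match_run, stage)
        )

    # stage 1: snoRNA, end-to-end, <= 1 mismatch
    if refs.snorna:
        sno_index = _RefIndex(refs.snorna)
        for rid, seq in pool:
            hit = _end_to_end_scan(seq, sno_index, max_mismatch=1)
            if hit is not None:
                _assign(rid, "snoRNA", hit, "snoRNA")
    else:
        warnings.warn("no snoRNA references: stage skipped")

    # stage 2: genome screen — genome-mapped reads leave the pool
    def _is_genomic(rid: str, seq: str) -> bool:
        if genome_mapped is not None:
            return bool(genome_mapped(rid))
        if refs.genome:
            return any(seq in g for g in refs.genome.values())
        return False

    pool2 = [
        (rid, seq)
        for rid, seq in pool
        if not _is_genomic(rid, seq) and not (exclusive and rid in calls)
    ]

    # stage 3: miRNA — first 30 nt, local, seed 16, 17-25M on a mature region
    if refs.pre_mirna:
        mir_index = _RefIndex(refs.pre_mirna)
        for rid, seq in pool2:
            hit = _local_scan(seq[:30], mir_index, seed_len=16)
            if hit is None:
                continue
            if not (MIRNA_MIN_RUN <= hit.match_run <= MIRNA_MAX_RUN):
                continue
            if not _mature_overlap_ok(hit, refs.mature, mature_overlap_frac):
                continue
            _assign(rid, "miRNA", hit, "miRNA")
    else:
        warnings.warn("no pre-miRNA references: stage skipped")

    # stage 4: tsRNA — round 1 (40 nt, seed 30), round 2 (30 nt, seed 18)
    if refs.trna:
        trna_index = _RefIndex(refs.trna)
        pool3 = [
            (rid, seq)
            for rid, seq in pool2
            if not (exclusive and rid in calls)
        ]
        for rid, seq in pool3:
            hit = _local_scan(seq[:40], trna_index, seed_len=30)
            stage = "tsRNA_r1"
            if hit is None:
                hit = _local_scan(seq[:30], trna_index, seed_len=18)
                stage = "tsRNA_r2"
            if hit is not None:
                _assign(rid, "tsRNA", hit, stage)
    else:
        warnings.warn("no tRNA references: stage skipped")

    out: list[SmallRNACall] = []
    counts = {"snoRNA": 0, "miRNA": 0, "tsRNA": 0, "unassigned": 0}
    for rid, seq in pool:
        read_calls = calls.get(rid)
        if not read_calls:
            out.append(SmallRNACall(rid, "unassigned", None, 0, "none"))
            counts["unassigned"] += 1
            continue
        if exclusive:
            read_calls = read_calls[:1]
        for call in read_calls:
            out.append(call)
            counts[call.assigned_class] += 1
    return out, counts


def small_rna_rpm(
    counts: pd.DataFrame, totals: Optional[pd.Series] = None
) -> ExpressionMatrix:
    """RPM matrix from per-feature per-cell counts.

    The default denominator is the per-library total of class-assigned
    reads (the column sums); pass ``totals`` to normalize by total
    sequenced reads instead.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"library {bad!r} has zero total reads")
    rpm = counts.div(totals / 1e6, axis=1)
    return ExpressionMatrix(rpm.astype(float))
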