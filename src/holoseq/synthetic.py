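"""Synthetic-data generators planting known ground truth for every stage.

Every generator is a pure function of (configuration, seed): the same seed
reproduces byte-identical output.  The generators emulate, at desk scale,
the data structures a carrier-assisted single-cell RNA-seq experiment
produces — stranded exonic reads with configurable coverage bias, carrier
reads, barcoded PCR libraries, small-RNA read pools of known class
composition, stranded antisense read sets, and dual (mRNA + miRNA)
single-cell expression matrices with planted subpopulations, miRNA->target
repression, and super-enhancer co-regulation blocks.

Expression noise model: per-feature baselines on a log2 scale, per-cell
size factors, Gaussian biological noise, then Poisson sampling of
2**log-expression.  This is the minimal model under which detection
thresholds (RPKM/RPM cutoffs) and rank-correlation filters behave as they
do on real libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from holoseq.io import (
    AlignmentRecord,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
)
from holoseq.smallrna import SmallRNARefs

BARCODE_LEN = 8
_BASES = "ACGT"

# 3' adapter used to fill small-RNA reads to 50 nt
ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGC"


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside simulated data."""

    planted_antisense: list[GenomicInterval] = field(default_factory=list)
    mirna_targets: list[tuple[str, str, float]] = field(default_factory=list)
    subpop_labels: dict[str, str] = field(default_factory=dict)
    se_blocks: list[tuple[str, list[str]]] = field(default_factory=list)
    read_labels: dict[str, str] = field(default_factory=dict)
    molecules_per_position: dict[tuple[str, int, str], int] = field(default_factory=dict)
    barcode_lineage: list[tuple[tuple[str, int, str], str]] = field(default_factory=list)
    marker_features: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _barcode_string(idx: int) -> str:
    chars = []
    for _ in range(BARCODE_LEN):
        chars.append(_BASES[idx % 4])
        idx //= 4
    return "".join(chars)


# ---------------------------------------------------------------------------
# stranded alignment libraries with coverage bias

PROFILES = ("uniform", "five_prime", "three_prime", "central_dropout")


def _bias_weights(L: int, profile: str) -> np.ndarray:
    """Per-bp sampling weight over transcript positions (t = fraction of the
    distance from the 5' end).  central_dropout applies the U-shaped weight
    eps + (1-eps)*(2t-1)^2 (eps = 0.05) to transcripts longer than 10 kb."""
    t = (np.arange(L) + 0.5) / L
    if profile == "uniform":
        w = np.ones(L)
    elif profile == "five_prime":
        w = np.exp(-4.0 * t)
    elif profile == "three_prime":
        w = np.exp(-4.0 * (1.0 - t))
    elif profile == "central_dropout":
        if L > 10_000:
            eps = 0.05
            w = eps + (1.0 - eps) * (2.0 * t - 1.0) ** 2
        else:
            w = np.ones(L)
    else:
        raise ValueError(f"unknown coverage profile {profile!r}")
    return w / w.sum()


def _transcript_to_blocks(
    gene: GeneModel, offset: int, length: int, strand: str
) -> tuple[GenomicInterval, tuple[GenomicInterval, ...]]:
    """Map a merged-exon offset range (genomic orientation) to genomic blocks."""
    blocks = []
    acc = 0
    lo, hi = offset, offset + length
    for e in gene.exons:
        e_lo, e_hi = acc, acc + len(e)
        s = max(lo, e_lo)
        t = min(hi, e_hi)
        if s < t:
            blocks.append(
                GenomicInterval(gene.chrom, e.start + s - e_lo, e.start + t - e_lo, strand)
            )
        acc = e_hi
    interval = GenomicInterval(gene.chrom, blocks[0].start, blocks[-1].end, strand)
    return interval, tuple(blocks)


def simulate_alignment_library(
    genes: Sequence[GeneModel],
    profile: str = "uniform",
    depth: int = 10_000,
    carrier_fraction: float = 0.0,
    antisense_rate: float = 0.0,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Simulate a stranded exonic read library with a named coverage bias.

    Reads are placed along the merged exons of each gene (gene picked with
    probability proportional to exon length, start position per the bias
    profile over the transcript, read truncated at the transcript end).
    A ``carrier_fraction`` of reads comes from the carrier reference (its
    own contig, never overlapping the genome); reads flip to the antisense
    strand at ``antisense_rate`` (default 0).  Emitted read count equals
    ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0 <= carrier_fraction < 1):
        raise ValueError("carrier_fraction must be in [0, 1)")
    if profile not in PROFILES:
        raise ValueError(f"unknown coverage profile {profile!r}")
    rng = np.random.default_rng(seed)
    truth = SimTruth(metadata={"seed": seed, "profile": profile, "depth": depth})
    lengths = np.array([g.exon_length for g in genes], dtype=float)
    gene_p = lengths / lengths.sum()
    weights = [None] * len(genes)
    records: list[AlignmentRecord] = []
    is_carrier = rng.random(depth) < carrier_fraction
    gene_idx = rng.choice(len(genes), size=depth, p=gene_p)
    flip = rng.random(depth) < antisense_rate
    for i in range(depth):
        rid = f"read{i:07d}"
        if is_carrier[i]:
            start = int(rng.integers(0, 100_000))
            iv = GenomicInterval("carrier", start, start + read_len, "+")
            records.append(
                AlignmentRecord(rid, iv, match_run=read_len, source_ref="carrier")
            )
            truth.read_labels[rid] = "carrier"
            continue
        g = genes[int(gene_idx[i])]
        L = g.exon_length
        if weights[gene_idx[i]] is None:
            # weights are defined along the transcript (5'->3'); convert to
            # genomic orientation for minus-strand genes
            w = _bias_weights(L, profile)
            if g.strand == "-":
                w = w[::-1]
            weights[gene_idx[i]] = w
        offset = int(rng.choice(L, p=weights[gene_idx[i]]))
        length = min(read_len, L - offset)
        strand = g.strand
        if flip[i]:
            strand = "-" if strand == "+" else "+"
        iv, blocks = _transcript_to_blocks(g, offset, length, strand)
        records.append(
            AlignmentRecord(rid, iv, match_run=length, blocks=blocks)
        )
        truth.read_labels[rid] = ("antisense:" if flip[i] else "gene:") + g.gene_id
    return records, truth


# ---------------------------------------------------------------------------
# barcoded PCR libraries


def simulate_barcoded_library(
    n_positions: int,
    templates_per_position: int = 10,
    cycles: int = 10,
    n_barcodes: int = 4**BARCODE_LEN,
    reads_sampled: int = 0,
    seed: int = 0,
    position_spacing: int = 100,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Simulate a degenerate-barcode PCR library.

    Each template molecule at each position draws one barcode uniformly at
    the priming event and doubles once per amplification cycle; sampled
    reads carry (position, barcode).  Truth records the true molecule count
    per position and the per-molecule barcode lineage.
    """
    if templates_per_position < 1:
        raise ValueError("templates_per_position must be >= 1")
    if not (1 <= n_barcodes <= 4**BARCODE_LEN):
        raise ValueError(f"n_barcodes must be in [1, 4^{BARCODE_LEN}]")
    rng = np.random.default_rng(seed)
    n_templates = n_positions * templates_per_position
    copies_per_template = 2**cycles
    pool_size = n_templates * copies_per_template
    if reads_sampled > pool_size:
        raise ValueError(
            f"reads_sampled {reads_sampled} exceeds amplified pool {pool_size}"
        )
    barcode_idx = rng.integers(0, n_barcodes, size=n_templates)
    truth = SimTruth(
        metadata={
            "seed": seed,
            "cycles": cycles,
            "n_barcodes": n_barcodes,
            "pool_size": pool_size,
        }
    )
    positions = []
    for p in range(n_positions):
        key = ("chr1", p * position_spacing, "+")
        positions.append(key)
        truth.molecules_per_position[key] = templates_per_position
    for t in range(n_templates):
        key = positions[t // templates_per_position]
        truth.barcode_lineage.append((key, _barcode_string(int(barcode_idx[t]))))
    records: list[AlignmentRecord] = []
    if reads_sampled > 0:
        counts = np.full(n_templates, copies_per_template, dtype=np.int64)
        drawn = rng.multivariate_hypergeometric(counts, reads_sampled)
        j = 0
        for t, k in enumerate(drawn):
            key, bc = truth.barcode_lineage[t]
            chrom, start, strand = key
            for _ in range(int(k)):
                iv = GenomicInterval(chrom, start, start + 50, strand)
                records.append(
                    AlignmentRecord(f"bcread{j:07d}", iv, match_run=50, barcode=bc)
                )
                j += 1
    return records, truth


# ---------------------------------------------------------------------------
# small-RNA read pools


def make_small_rna_refs(
    n_snorna: int = 8,
    n_mirna: int = 10,
    n_trna: int = 8,
    seed: int = 0,
) -> SmallRNARefs:
    """Random reference set for cascade tests: snoRNAs (80-200 nt),
    pre-miRNAs (70-90 nt with one 20-23 nt mature interval), tRNAs (72-76 nt)."""
    rng = np.random.default_rng(seed)

    def _seq(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))

    snorna = {f"SNORD{i:03d}": _seq(int(rng.integers(80, 201))) for i in range(n_snorna)}
    pre_mirna = {}
    mature = {}
    for i in range(n_mirna):
        mid = f"mir-{i:03d}"
        L = int(rng.integers(70, 91))
        pre_mirna[mid] = _seq(L)
        m_len = int(rng.integers(20, 24))
        m_start = int(rng.integers(1, L - m_len))
        mature[mid] = [(m_start, m_start + m_len)]
    trna = {f"tRNA-{i:03d}": _seq(int(rng.integers(72, 77))) for i in range(n_trna)}
    return SmallRNARefs(snorna=snorna, pre_mirna=pre_mirna, mature=mature, trna=trna)


def _fill_read(insert: str, continuation: Optional[str], read_len: int, rng) -> str:
    """Pad an insert to read_len with the 3' adapter; the first fill base is
    forced to differ from the reference continuation so a perfect match can
    never extend past the insert."""
    if len(insert) >= read_len:
        return insert[:read_len]
    fill = ADAPTER[: read_len - len(insert)]
    if continuation is not None and fill and fill[0] == continuation:
        alternatives = [b for b in _BASES if b != continuation]
        fill = alternatives[int(rng.integers(0, 3))] + fill[1:]
    return insert + fill


def simulate_small_rna_pool(
    refs: SmallRNARefs,
    composition: dict[str, float],
    n_reads: int = 10_000,
    error_rate: float = 0.0,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate a 50-nt small-RNA read pool of known class composition.

    miRNA reads copy 17-25 nt of a mature region; tsRNA reads copy 28-40 nt
    5' or 3' tRNA halves; snoRNA reads copy 50-nt snoRNA subsequences (so
    they survive an end-to-end screen).  Shorter inserts are 3'-filled with
    adapter sequence.  ``error_rate`` is a per-base substitution rate.
    """
    fractions = dict(composition)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    for cls in fractions:
        if cls not in ("miRNA", "tsRNA", "snoRNA"):
            raise ValueError(f"unknown small-RNA class {cls!r}")
    rng = np.random.default_rng(seed)
    classes = sorted(fractions)
    probs = np.array([fractions[c] for c in classes])
    truth = SimTruth(metadata={"seed": seed, "composition": fractions})
    reads: list[tuple[str, str]] = []
    if n_reads == 0:
        return reads, truth
    draw = rng.choice(len(classes), size=n_reads, p=probs)
    sno_ids = sorted(refs.snorna)
    mir_ids = sorted(refs.pre_mirna)
    trna_ids = sorted(refs.trna)
    for i in range(n_reads):
        cls = classes[int(draw[i])]
        rid = f"sr{i:06d}"
        if cls == "snoRNA":
            sid = sno_ids[int(rng.integers(0, len(sno_ids)))]
            ref = refs.snorna[sid]
            start = int(rng.integers(0, len(ref) - read_len + 1))
            seq = ref[start : start + read_len]
        elif cls == "miRNA":
            mid = mir_ids[int(rng.integers(0, len(mir_ids)))]
            ref = refs.pre_mirna[mid]
            m_start, m_end = refs.mature[mid][
                int(rng.integers(0, len(refs.mature[mid])))
            ]
            m_len = m_end - m_start
            if m_len < 17:
                raise ValueError(f"mature region of {mid!r} shorter than 17 nt")
            ins_len = int(rng.integers(17, min(25, m_len) + 1))
            ins_start = m_start + int(rng.integers(0, m_len - ins_len + 1))
            insert = ref[ins_start : ins_start + ins_len]
            cont = ref[ins_start + ins_len] if ins_start + ins_len < len(ref) else None
            seq = _fill_read(insert, cont, read_len, rng)
        else:  # tsRNA
            tid = trna_ids[int(rng.integers(0, len(trna_ids)))]
            ref = refs.trna[tid]
            ins_len = int(rng.integers(28, min(40, len(ref)) + 1))
            if rng.random() < 0.5:
                insert = ref[:ins_len]
                cont = ref[ins_len] if ins_len < len(ref) else None
            else:
                insert = ref[len(ref) - ins_len :]
                cont = None  # 3' half ends at the reference end
            seq = _fill_read(insert, cont, read_len, rng)
        if error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < error_rate:
                    chars[j] = _BASES[int(rng.integers(0, 4))]
            seq = "".join(chars)
        reads.append((rid, seq))
        truth.read_labels[rid] = cls
    return reads, truth


# ---------------------------------------------------------------------------
# dual single-cell transcriptomes


DEFAULT_NOISE = {
    "gene_noise_sd": 0.5,
    "cell_sd": 0.2,
    "repression_noise_sd": 0.3,
    "se_noise_sd": 0.3,
}


def default_subpop_spec(n_cells: int = 32) -> dict:
    sizes = {}
    base = n_cells // 3
    sizes["I"] = base + (1 if n_cells % 3 > 0 else 0)
    sizes["II"] = base + (1 if n_cells % 3 > 1 else 0)
    sizes["III"] = base
    # most top-variant features in a clustered tumor dataset are themselves
    # subpopulation-differential (the featured transcript groups span the
    # bulk of the selected features), so markers cover most of the feature
    # space at a moderate (1.5 log2-unit) shift
    return {
        "sizes": sizes,
        "n_marker_genes": 120,
        "gene_shift": 1.5,
        "n_marker_mirnas": 15,
        "mirna_shift": 1.5,
    }


def default_repression_spec(
    n_edges: int = 8,
    beta: float = 2.0,
    n_genes: int = 500,
    n_mirnas: int = 60,
) -> list[tuple[str, str, float]]:
    # ids from the tail of the id space, clear of subpopulation markers
    # (head) and SE blocks (middle)
    return [
        (f"sim-mir-{n_mirnas - 1 - i:03d}", f"gene{n_genes - 1 - i:04d}", beta)
        for i in range(n_edges)
    ]


def default_se_spec(
    n_blocks: int = 6,
    genes_per_block: int = 8,
    n_genes: int = 500,
    n_mirnas: int = 60,
) -> list[dict]:
    patterns = [
        {"I": 2.0, "II": 0.0, "III": -2.0},
        {"I": -2.0, "II": 2.0, "III": 0.0},
        {"I": 0.0, "II": -2.0, "III": 2.0},
        {"I": 2.0, "II": -2.0, "III": 0.0},
        {"I": 0.0, "II": 2.0, "III": -2.0},
        {"I": -2.0, "II": 0.0, "III": 2.0},
    ]
    gene_start = n_genes - 20 - n_blocks * genes_per_block  # below repression ids
    mirna_start = n_mirnas - 9 - n_blocks
    blocks = []
    for b in range(n_blocks):
        members = [
            f"gene{gene_start + b * genes_per_block + j:04d}"
            for j in range(genes_per_block)
        ]
        members.append(f"sim-mir-{mirna_start + b:03d}")
        blocks.append(
            {
                "se_id": f"SE{b:03d}",
                "members": members,
                "group_means": patterns[b % len(patterns)],
            }
        )
    return blocks


def simulate_dual_transcriptome(
    n_cells: int = 32,
    n_genes: int = 500,
    n_mirnas: int = 60,
    subpop_spec: Optional[dict] = None,
    repression_spec: Optional[list[tuple[str, str, float]]] = None,
    se_spec: Optional[list[dict]] = None,
    noise_model: Optional[dict] = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Simulate paired mRNA and miRNA single-cell matrices.

    Plants (1) cell subpopulations with per-group log2-mean shifts on marker
    features, (2) miRNA->target repression: target log2-expression =
    baseline - beta*(centered miRNA log2-expression) + noise, and (3)
    super-enhancer blocks whose members share a latent per-cell activity.
    Values are Poisson samples of 2**log-expression (non-negative).
    """
    if subpop_spec is None:
        subpop_spec = default_subpop_spec(n_cells)
    if repression_spec is None:
        repression_spec = default_repression_spec(n_genes=n_genes, n_mirnas=n_mirnas)
    if se_spec is None:
        se_spec = default_se_spec(n_genes=n_genes, n_mirnas=n_mirnas)
    noise = dict(DEFAULT_NOISE)
    if noise_model:
        noise.update(noise_model)
    sizes = subpop_spec["sizes"]
    if len(sizes) < 2:
        raise ValueError("subpop_spec must assign >= 2 groups")
    if sum(sizes.values()) != n_cells:
        raise ValueError("subpop sizes must sum to n_cells")
    rng = np.random.default_rng(seed)

    cell_ids = [f"cell{c:03d}" for c in range(n_cells)]
    labels: dict[str, str] = {}
    c = 0
    for grp in sizes:
        for _ in range(sizes[grp]):
            labels[cell_ids[c]] = grp
            c += 1
    groups = list(sizes)

    # feature id layout: markers at the head, SE blocks and repression
    # targets at the tail (see default_se_spec / default_repression_spec)
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    mirna_ids = [f"sim-mir-{m:03d}" for m in range(n_mirnas)]
    known = set(gene_ids) | set(mirna_ids)
    for mid, gid, _ in repression_spec:
        if mid not in known or gid not in known:
            raise ValueError(f"repression edge ({mid}, {gid}) names absent features")
    for block in se_spec:
        for f in block["members"]:
            if f not in known:
                raise ValueError(f"SE block {block['se_id']} names absent feature {f!r}")

    n_mark_g = subpop_spec.get("n_marker_genes", 0)
    n_mark_m = subpop_spec.get("n_marker_mirnas", 0)
    marker_genes = {
        grp: gene_ids[i * n_mark_g : (i + 1) * n_mark_g] for i, grp in enumerate(groups)
    }
    marker_mirnas = {
        grp: mirna_ids[i * n_mark_m : (i + 1) * n_mark_m] for i, grp in enumerate(groups)
    }

    cell_factor = rng.normal(0.0, noise["cell_sd"], size=n_cells)
    gene_base = rng.uniform(3.0, 8.0, size=len(gene_ids))
    mirna_base = rng.uniform(4.0, 7.0, size=len(mirna_ids))

    log_gene = (
        gene_base[:, None]
        + cell_factor[None, :]
        + rng.normal(0.0, noise["gene_noise_sd"], size=(len(gene_ids), n_cells))
    )
    log_mirna = (
        mirna_base[:, None]
        + cell_factor[None, :]
        + rng.normal(0.0, noise["gene_noise_sd"], size=(len(mirna_ids), n_cells))
    )
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mirna_pos = {m: i for i, m in enumerate(mirna_ids)}
    cell_grp = np.array([groups.index(labels[c]) for c in cell_ids])

    for gi, grp in enumerate(groups):
        mask = cell_grp == gi
        for g in marker_genes[grp]:
            log_gene[gene_pos[g], mask] += subpop_spec.get("gene_shift", 2.0)
        for m in marker_mirnas[grp]:
            log_mirna[mirna_pos[m], mask] += subpop_spec.get("mirna_shift", 2.0)

    # super-enhancer blocks: shared latent activity per cell
    truth = SimTruth(metadata={"seed": seed}, subpop_labels=labels)
    for block in se_spec:
        means = block["group_means"]
        activity = np.array(
            [means.get(labels[c], 0.0) for c in cell_ids]
        ) + rng.normal(0.0, noise["se_noise_sd"], size=n_cells)
        for f in block["members"]:
            if f in mirna_pos:
                log_mirna[mirna_pos[f]] += activity
            elif f in gene_pos:
                log_gene[gene_pos[f]] += activity
        truth.se_blocks.append((block["se_id"], list(block["members"])))

    # miRNA -> target repression (overrides the target's independent noise)
    for mid, gid, beta in repression_spec:
        if mid not in mirna_pos or gid not in gene_pos:
            raise ValueError(f"repression edge ({mid}, {gid}) names absent features")
        m_log = log_mirna[mirna_pos[mid]]
        base = gene_base[gene_pos[gid]] + cell_factor
        log_gene[gene_pos[gid]] = (
            base
            - beta * (m_log - m_log.mean())
            + rng.normal(0.0, noise["repression_noise_sd"], size=n_cells)
        )
        truth.mirna_targets.append((mid, gid, beta))

    mrna_vals = rng.poisson(np.power(2.0, np.clip(log_gene, None, 20.0))).astype(float)
    mirna_vals = rng.poisson(np.power(2.0, np.clip(log_mirna, None, 20.0))).astype(float)

    gene_lengths = pd.Series(
        rng.integers(500, 5000, size=len(gene_ids)), index=gene_ids
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_vals, index=gene_ids, columns=cell_ids),
        pd.Series("mRNA", index=gene_ids),
        gene_lengths,
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirna_ids, columns=cell_ids),
        pd.Series("miRNA", index=mirna_ids),
        pd.Series(22, index=mirna_ids),
    )
    truth.marker_features = {
        f"genes_{grp}": list(marker_genes[grp]) for grp in groups
    } | {f"mirnas_{grp}": list(marker_mirnas[grp]) for grp in groups}
    return mrna, mirna, truth


# ---------------------------------------------------------------------------
# stranded antisense datasets


def simulate_antisense_dataset(
    genes: Sequence[GeneModel],
    planted: Sequence[GenomicInterval],
    reads_per_antisense: int = 100,
    background_rate: float = 0.0,
    read_len: int = 50,
    genome_length: Optional[int] = None,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Simulate stranded reads with planted antisense transcription units.

    Antisense reads fall uniformly inside each planted interval (on its own
    strand, which must be opposite every overlapping gene — a planted
    interval overlapping a same-strand gene is an error).  Uniform
    background reads are added at ``background_rate`` per bp per strand.
    """
    rng = np.random.default_rng(seed)
    for p in planted:
        for g in genes:
            if g.strand == p.strand and p.overlap(g.interval) > 0:
                raise ValueError(
                    f"planted interval {p} overlaps same-strand gene {g.gene_id}"
                )
    if genome_length is None:
        ends = [g.interval.end for g in genes] + [p.end for p in planted]
        genome_length = (max(ends) if ends else 0) + 10_000
    records: list[AlignmentRecord] = []
    truth = SimTruth(
        planted_antisense=list(planted),
        metadata={"seed": seed, "genome_length": genome_length},
    )
    i = 0
    for k, p in enumerate(planted):
        for _ in range(reads_per_antisense):
            start = int(rng.integers(p.start, max(p.start + 1, p.end - read_len + 1)))
            iv = GenomicInterval(p.chrom, start, start + read_len, p.strand)
            rid = f"as{i:07d}"
            records.append(AlignmentRecord(rid, iv, match_run=read_len))
            truth.read_labels[rid] = f"antisense:{k}"
            i += 1
    if background_rate > 0:
        chrom = genes[0].chrom if genes else (planted[0].chrom if planted else "chr1")
        for strand in ("+", "-"):
            n_bg = rng.poisson(background_rate * genome_length)
            starts = rng.integers(0, max(1, genome_length - read_len), size=n_bg)
            for s in np.sort(starts):
                rid = f"bg{i:07d}"
                iv = GenomicInterval(chrom, int(s), int(s) + read_len, strand)
                records.append(AlignmentRecord(rid, iv, match_run=read_len))
                truth.read_labels[rid] = "background"
                i += 1
    return records, truth


def default_antisense_scenario(
    n_genes: int = 10,
    gene_len: int = 2_000,
    spacing: int = 10_000,
    antisense_len: int = 2_000,
    overlap: int = 1_000,
    seed: int = 0,
) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """A window-grid-friendly genome: single-exon genes on the + strand every
    ``spacing`` bp, each with one planted antisense unit on the - strand
    overlapping the gene's 3' half (default 50% of the antisense length, so
    called islands survive both the >=20% opposite-overlap rule and the
    >80% opposite-cover drop filter)."""
    genes = []
    planted = []
    for k in range(n_genes):
        start = (k + 1) * spacing
        iv = GenomicInterval("chr1", start, start + gene_len, "+")
        genes.append(GeneModel(f"g{k:03d}", iv, (iv,)))
        a_start = start + gene_len - overlap
        planted.append(
            GenomicInterval("chr1", a_start, a_start + antisense_len, "-")
        )
    return genes, planted
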