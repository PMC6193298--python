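"""Transcriptional-bursting statistics and top-variant feature selection.

The Fano factor (variance/mean) of per-cell RPKM values measures bursting;
computed separately on exonic (mRNA) and intronic (pre-mRNA) signal it
contrasts transcriptional kinetics between gene classes.  Feature
selection for clustering uses the inverse dispersion index V = u/s^2 on
log2(x+1)-transformed expression, ranked ascending (small V = most
variable relative to its mean) after excluding low-expressed (u < 1) and
constant features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from holoseq.io import ExpressionMatrix


@dataclass
class GeneBurstStats:
    gene_id: str
    mrna_rpkm: np.ndarray
    intron_rpkm: np.ndarray
    mrna_fano: float
    intron_fano: float
    mean_mrna: float


@dataclass(frozen=True)
class VariabilityScore:
    feature_id: str
    u: float
    s: float
    V: float


def fano(values: Sequence[float]) -> float:
    """Sample variance (n-1 denominator) divided by the mean; the mean must
    be positive."""
    arr = np.asarray(values, dtype=float)
    m = arr.mean()
    if m <= 0:
        raise ValueError("fano factor undefined for non-positive mean")
    return float(arr.var(ddof=1) / m)


def _cells_threshold(n_cells: int) -> int:
    # the reference selection uses "at least 5 of 10 cells"; scale as
    # ceil(n/2) for other cell counts
    return 5 if n_cells == 10 else math.ceil(n_cells / 2)


def select_bursting_genes(
    mrna_rpkm: pd.DataFrame,
    intron_rpkm: pd.DataFrame,
    exon_counts: pd.DataFrame,
    intron_counts: pd.DataFrame,
    intron_lengths: pd.Series,
    rpkm_threshold: float = 0.1,
    min_exon_reads: int = 5,
    min_intron_reads: int = 1,
    min_intron_length: int = 1000,
    min_cells: Optional[int] = None,
) -> list[str]:
    """Genes eligible for bursting statistics.  All thresholds are strict:

    (a) mRNA RPKM > 0.1 and intron RPKM > 0.1, each in >= min_cells cells;
    (b) sense exon reads > 5 and sense intron reads > 1, each in >=
        min_cells cells;
    (c) intron length > 1000 bp.
    """
    n_cells = mrna_rpkm.shape[1]
    if min_cells is None:
        min_cells = _cells_threshold(n_cells)
    idx = mrna_rpkm.index
    ok = pd.Series(True, index=idx)
    ok &= (mrna_rpkm > rpkm_threshold).sum(axis=1) >= min_cells
    ok &= (intron_rpkm.reindex(idx, fill_value=0) > rpkm_threshold).sum(axis=1) >= min_cells
    ok &= (exon_counts.reindex(idx, fill_value=0) > min_exon_reads).sum(axis=1) >= min_cells
    ok &= (intron_counts.reindex(idx, fill_value=0) > min_intron_reads).sum(axis=1) >= min_cells
    ok &= intron_lengths.reindex(idx, fill_value=0) > min_intron_length
    return list(idx[ok])


def burst_stats(
    gene_ids: Iterable[str],
    mrna_rpkm: pd.DataFrame,
    intron_rpkm: pd.DataFrame,
) -> list[GeneBurstStats]:
    """Fano factors of mRNA and intron RPKM per gene across cells."""
    out = []
    for gid in gene_ids:
        mr = mrna_rpkm.loc[gid].to_numpy(dtype=float)
        ir = intron_rpkm.loc[gid].to_numpy(dtype=float)
        out.append(
            GeneBurstStats(
                gene_id=gid,
                mrna_rpkm=mr,
                intron_rpkm=ir,
                mrna_fano=fano(mr),
                intron_fano=fano(ir),
                mean_mrna=float(mr.mean()),
            )
        )
    return out


def variability_scores(
    matrix: ExpressionMatrix, u_floor: float = 1.0
) -> list[VariabilityScore]:
    """V = u/s^2 on log2(x+1)-transformed values; features with u < u_floor
    or zero variance are excluded."""
    log = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    u = log.mean(axis=1)
    s = log.std(axis=1, ddof=1)
    out = []
    for fid, ui, si in zip(matrix.feature_ids, u, s):
        if ui < u_floor or si == 0:
            continue
        out.append(VariabilityScore(fid, float(ui), float(si), float(ui / si**2)))
    return out


def top_variant_features(
    matrix: ExpressionMatrix,
    n_top: int,
    u_floor: float = 1.0,
    must_include: Optional[Sequence[str]] = None,
) -> list[str]:
    """The n_top most variable features by ascending V = u/s^2 (ties broken
    by feature id).  ``must_include`` ids are appended if eligible and not
    already selected."""
    scores = variability_scores(matrix, u_floor)
    ranked = sorted(scores, key=lambda v: (v.V, v.feature_id))
    if n_top > len(ranked):
        warnings.warn(
            f"n_top={n_top} exceeds {len(ranked)} eligible features; returning all"
        )
    selected = [v.feature_id for v in ranked[:n_top]]
    if must_include:
        present = set(selected)
        for fid in must_include:
            if fid not in present and fid in matrix.values.index:
                selected.append(fid)
                present.add(fid)
    return selected
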