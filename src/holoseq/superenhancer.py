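"""Super-enhancer feature association and per-cell activity scoring.

Each super-enhancer (SE) is associated with the closest gene and the
closest miRNA (or miRNA cluster) whose transcription start lies within
+/- 100 kb of the SE interval.  The expression of SE-associated features
across cells yields a cell-by-cell Spearman correlation matrix; gene-group
activity per cell is the median per-feature z-score (Group_Exp), min-max
scaled to [0, 1]:

    Group_Act_i = (Group_Exp_i - Group_Exp_min) / (Group_Exp_max - Group_Exp_min)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from holoseq.io import ExpressionMatrix, GeneModel, GenomicInterval


@dataclass
class SuperEnhancer:
    se_id: str
    interval: GenomicInterval
    associated_gene: Optional[str] = None
    associated_mirna: Optional[str] = None
    mirna_cluster: list[str] = field(default_factory=list)


@dataclass
class GroupActivity:
    group_id: str
    group_exp: pd.Series
    group_act: pd.Series
    exp_min: float
    exp_max: float


def tss(gene: GeneModel) -> int:
    """Transcription start: 5' end of the gene interval, strand-aware."""
    return gene.interval.end - 1 if gene.strand == "-" else gene.interval.start


def _interval_distance(anchor: int, iv: GenomicInterval) -> int:
    if anchor < iv.start:
        return iv.start - anchor
    if anchor >= iv.end:
        return anchor - (iv.end - 1)
    return 0


def cluster_mirnas(
    mirnas: Sequence[GeneModel], cluster_window: int = 10_000
) -> list[list[GeneModel]]:
    """Single-linkage clusters of miRNAs whose anchors lie within
    ``cluster_window`` of each other on one chrom."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in mirnas:
        by_chrom.setdefault(m.chrom, []).append(m)
    clusters = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=tss)
        cur = [ms[0]]
        for m in ms[1:]:
            if tss(m) - tss(cur[-1]) <= cluster_window:
                cur.append(m)
            else:
                clusters.append(cur)
                cur = [m]
        clusters.append(cur)
    return clusters


def associate_se(
    se_intervals: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    mirnas: Sequence[GeneModel],
    window: int = 100_000,
    cluster_window: int = 10_000,
    overrides: Optional[dict[str, str]] = None,
) -> list[SuperEnhancer]:
    """Associate each SE with its closest gene and miRNA (cluster) within
    +/- ``window`` bp of the SE interval.

    Distance is measured from the feature's transcription start to the SE
    interval (0 when the TSS lies inside); ties go to the smaller feature
    start coordinate.  miRNAs within ``cluster_window`` of each other share
    one association (the nearest member represents the cluster).
    ``overrides`` maps se_id to a feature id, replacing the automatic call
    (manual curation support).
    """
    overrides = overrides or {}
    mirna_clusters = cluster_mirnas(mirnas, cluster_window) if mirnas else []
    out = []
    for se_id, se_iv in se_intervals:
        best_gene = None
        best_key = None
        for g in genes:
            if g.chrom != se_iv.chrom:
                continue
            d = _interval_distance(tss(g), se_iv)
            if d > window:
                continue
            key = (d, g.interval.start, g.gene_id)
            if best_key is None or key < best_key:
                best_key, best_gene = key, g.gene_id
        best_mirna = None
        best_members: list[str] = []
        best_key = None
        for cluster in mirna_clusters:
            if cluster[0].chrom != se_iv.chrom:
                continue
            dists = [(_interval_distance(tss(m), se_iv), m.interval.start, m.gene_id) for m in cluster]
            d, start, mid = min(dists)
            if d > window:
                continue
            key = (d, start, mid)
            if best_key is None or key < best_key:
                best_key = key
                best_mirna = mid
                best_members = [m.gene_id for m in cluster]
        se = SuperEnhancer(se_id, se_iv, best_gene, best_mirna, best_members)
        if se_id in overrides:
            fid = overrides[se_id]
            if fid in {m.gene_id for m in mirnas}:
                se.associated_mirna = fid
                se.mirna_cluster = [fid]
            else:
                se.associated_gene = fid
        out.append(se)
    return out


def se_cell_correlation(
    matrix: pd.DataFrame, cell_order: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Cell-by-cell Spearman correlation over SE-associated features.

    Cells are ordered per the given ranking (e.g. by expression
    subpopulation).  Cells with a constant profile get NaN rows/columns;
    the diagonal of defined cells is exactly 1.
    """
    if matrix.shape[0] < 4:
        raise ValueError("need >= 4 SE-associated features")
    sub = matrix[list(cell_order)] if cell_order is not None else matrix
    corr = sub.corr(method="spearman")
    const = sub.nunique(axis=0) <= 1
    for cell in sub.columns[const]:
        corr.loc[cell, :] = np.nan
        corr.loc[:, cell] = np.nan
    for cell in sub.columns[~const]:
        corr.loc[cell, cell] = 1.0
    return corr


def group_expression(
    matrix: pd.DataFrame, members: Sequence[str], log_transform: bool = False
) -> pd.Series:
    """Per-cell group expression: per-feature z-score across cells (sample
    sd), then the per-cell median over the group members.

    The matrix is expected on the log2(x+1) scale; set ``log_transform`` to
    apply the transform here.  Zero-variance members are dropped; an empty
    (or all-constant) member set is an error.
    """
    members = [m for m in members if m in matrix.index]
    if not members:
        raise ValueError("empty member set")
    sub = matrix.loc[members].astype(float)
    if log_transform:
        sub = np.log2(sub + 1.0)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all group members have zero variance across cells")
    z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z.median(axis=0)


def group_activity(group_exp: pd.Series) -> pd.Series:
    """Min-max scaling of per-cell group expression to [0, 1]; when all
    cells are equal, every cell gets 0.5 with a warning."""
    lo, hi = float(group_exp.min()), float(group_exp.max())
    if hi == lo:
        warnings.warn("group expression constant across cells; activity set to 0.5")
        return pd.Series(0.5, index=group_exp.index)
    return (group_exp - lo) / (hi - lo)


def score_groups(
    matrix: pd.DataFrame, groups: dict[str, Sequence[str]], log_transform: bool = True
) -> list[GroupActivity]:
    """Group_Exp and Group_Act for each named feature group."""
    out = []
    for gid, members in groups.items():
        exp = group_expression(matrix, members, log_transform=log_transform)
        act = group_activity(exp)
        out.append(
            GroupActivity(gid, exp, act, float(exp.min()), float(exp.max()))
        )
    return out
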