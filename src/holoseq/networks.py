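"""miRNA-target regulatory network inference by rank correlation.

Candidate edges come from an experimentally validated target catalog; the
cascade keeps a pair when both members pass a detection filter and their
expression across cells is significantly negatively correlated (Spearman
rho < 0, p < 0.05).  Two study variants add further stages: the oncomiR
module additionally requires both members to be differentially expressed
between cell subpopulation I and II+III (Welch one-tailed t test), and the
tumor-suppressor module excludes known oncomiRs and restricts detection
and correlation to the subpopulation II+III cells.

No multiple-testing correction is applied in the cascade (matching the
procedure this reimplements); a Benjamini-Hochberg option exists but is
off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from holoseq.io import ExpressionMatrix


@dataclass(frozen=True)
class TargetCatalog:
    """Validated (miRNA, target gene) pairs, unique by (mirna, gene)."""

    pairs: tuple[tuple[str, str, str], ...]  # (mirna_id, gene_id, evidence_class)

    def __post_init__(self) -> None:
        keys = [(m, g) for m, g, _ in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("catalog pairs must be unique by (mirna, gene)")

    @classmethod
    def from_tsv(cls, stream) -> "TargetCatalog":
        """Read a miRTarBase-like TSV with columns miRNA, Target Gene and an
        optional Support Type column."""
        import io as _io

        handle = _io.StringIO(stream) if isinstance(stream, str) else stream
        df = pd.read_csv(handle, sep="\t")
        cols = {c.lower().strip(): c for c in df.columns}
        mcol = cols.get("mirna", list(df.columns)[0])
        gcol = cols.get("target gene", list(df.columns)[1])
        scol = cols.get("support type")
        pairs = []
        seen = set()
        for _, row in df.iterrows():
            key = (str(row[mcol]), str(row[gcol]))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((*key, str(row[scol]) if scol else ""))
        return cls(tuple(pairs))


@dataclass
class NetworkEdge:
    mirna_id: str
    gene_id: str
    rho: float
    p: float
    p_exact: Optional[float] = None
    passed_filters: list[str] = field(default_factory=list)
    de_flags: Optional[dict[str, float]] = None


def filter_detected(
    matrix: pd.DataFrame,
    min_fraction: float = 1.0 / 3.0,
    scope_cells: Optional[Sequence[str]] = None,
) -> list[str]:
    """Features detected (value > 0) in at least ceil(min_fraction * n)
    of the scope cells.

    With 32 cells this keeps features nonzero in >= 11 cells (zero in at
    most 21); with 14 cells, nonzero in >= 5 (zero in at most 9).
    """
    sub = matrix[list(scope_cells)] if scope_cells is not None else matrix
    need = math.ceil(min_fraction * sub.shape[1])
    n_detected = (sub > 0).sum(axis=1)
    return list(sub.index[n_detected >= need])


def filter_detected_min_cells(
    counts: pd.DataFrame, min_reads: int = 1, min_cells: int = 2
) -> list[str]:
    """Features with >= min_reads in >= min_cells cells (the detection rule
    used for small dual-transcriptome cell sets)."""
    ok = (counts >= min_reads).sum(axis=1) >= min_cells
    return list(counts.index[ok])


@lru_cache(maxsize=4)
def _perm_index_matrix(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (average ranks)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ry_perms = ry[_perm_index_matrix(n)]
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    ry_c = ry_perms - ry_perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((ry_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ry_c @ rx_c) / (denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_edge(
    mirna_values: Sequence[float],
    gene_values: Sequence[float],
    exact_max_n: int = 9,
) -> tuple[float, float, Optional[float]]:
    """Spearman rho (average-rank method) and two-sided p.

    The primary p uses the t-approximation t = rho*sqrt((n-2)/(1-rho^2));
    for n <= exact_max_n an exact permutation p is computed alongside.
    Raises ValueError on zero variance in either vector.
    """
    x = np.asarray(mirna_values, dtype=float)
    y = np.asarray(gene_values, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: rho undefined")
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    p_exact = _exact_spearman_p(x, y, rho) if len(x) <= exact_max_n else None
    return rho, p, p_exact


def infer_negative_network(
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    catalog: TargetCatalog,
    scope_cells: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    detection: str = "fraction",
    min_fraction: float = 1.0 / 3.0,
    min_reads: int = 1,
    min_cells: int = 2,
    bh_correct: bool = False,
) -> list[NetworkEdge]:
    """Catalog pairs whose members are detected and negatively correlated.

    ``detection`` selects the detection rule: "fraction" (nonzero in >=
    1/3 of scope cells) or "min_cells" (>= min_reads in >= min_cells
    cells).  Edges are retained iff rho < 0 and p < alpha; no
    multiple-testing correction unless ``bh_correct``.
    """
    cells = list(scope_cells) if scope_cells is not None else list(gene_matrix.columns)
    if detection == "fraction":
        det_m = set(filter_detected(mirna_matrix, min_fraction, cells))
        det_g = set(filter_detected(gene_matrix, min_fraction, cells))
    elif detection == "min_cells":
        det_m = set(filter_detected_min_cells(mirna_matrix[cells], min_reads, min_cells))
        det_g = set(filter_detected_min_cells(gene_matrix[cells], min_reads, min_cells))
    else:
        raise ValueError(f"unknown detection rule {detection!r}")
    candidates = []
    for mid, gid, _ in catalog.pairs:
        if mid in det_m and gid in det_g:
            candidates.append((mid, gid))
    edges: list[NetworkEdge] = []
    for mid, gid in candidates:
        try:
            rho, p, p_exact = spearman_edge(
                mirna_matrix.loc[mid, cells], gene_matrix.loc[gid, cells]
            )
        except ValueError:
            continue
        edges.append(
            NetworkEdge(mid, gid, rho, p, p_exact, ["detected"])
        )
    if bh_correct and edges:
        order = np.argsort([e.p for e in edges])
        m = len(edges)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = order[m - 1 - rank]
            prev = min(prev, edges[i].p * m / (m - rank))
            adj[i] = prev
        for e, q in zip(edges, adj):
            e.p = float(q)
    retained = []
    for e in edges:
        if e.rho < 0 and e.p < alpha:
            e.passed_filters.append("negative_correlation")
            retained.append(e)
    return retained


def de_test(
    values_group_a: Sequence[float],
    values_group_b: Sequence[float],
    variant: str = "welch_one_tailed",
) -> float:
    """Two-sample t test in two study variants.

    ``welch_one_tailed``: unequal-variance statistic, one-tailed p in the
    direction of the observed group difference.  ``student_two_tailed``:
    pooled-variance statistic, two-tailed p.  Identical constant groups
    give p = 1.
    """
    a = np.asarray(values_group_a, dtype=float)
    b = np.asarray(values_group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 1.0
    if variant == "welch_one_tailed":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue) / 2.0
    if variant == "student_two_tailed":
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.pvalue)
    raise ValueError(f"unknown t-test variant {variant!r}")


def _split_by_subpop(
    cells: Sequence[str], subpop_labels: dict[str, str]
) -> tuple[list[str], list[str]]:
    group_a = [c for c in cells if subpop_labels[c] == "I"]
    group_b = [c for c in cells if subpop_labels[c] in ("II", "III")]
    return group_a, group_b


def oncomir_module(
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    catalog: TargetCatalog,
    oncomirs: Sequence[str],
    subpop_labels: dict[str, str],
    alpha: float = 0.05,
) -> list[NetworkEdge]:
    """OncomiR network: catalog restricted to the named oncomiRs, detection
    in >= 1/3 of all cells, negative Spearman correlation, and differential
    expression of both members between subpopulation I and II+III (Welch
    one-tailed, p < 0.05)."""
    present = [m for m in oncomirs if m in mirna_matrix.index]
    for m in oncomirs:
        if m not in mirna_matrix.index:
            warnings.warn(f"oncomir {m!r} absent from matrix; skipped")
    sub_catalog = TargetCatalog(
        tuple(p for p in catalog.pairs if p[0] in present)
    )
    cells = list(gene_matrix.columns)
    edges = infer_negative_network(
        mirna_matrix, gene_matrix, sub_catalog, cells, alpha=alpha
    )
    group_a, group_b = _split_by_subpop(cells, subpop_labels)
    out = []
    for e in edges:
        p_m = de_test(
            mirna_matrix.loc[e.mirna_id, group_a],
            mirna_matrix.loc[e.mirna_id, group_b],
            "welch_one_tailed",
        )
        p_g = de_test(
            gene_matrix.loc[e.gene_id, group_a],
            gene_matrix.loc[e.gene_id, group_b],
            "welch_one_tailed",
        )
        e.de_flags = {"mirna": p_m, "gene": p_g}
        if p_m < alpha and p_g < alpha:
            e.passed_filters.append("differential_expression")
            out.append(e)
    return out


def suppressor_module(
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    catalog: TargetCatalog,
    exclude_mirnas: Sequence[str],
    subpop_subset: Sequence[str],
    alpha: float = 0.05,
) -> list[NetworkEdge]:
    """Tumor-suppressor-miRNA network: known oncomiR interactions removed,
    detection and negative-correlation filters applied within the
    subpopulation II+III cell subset only (no differential-expression
    stage)."""
    if not list(subpop_subset):
        raise ValueError("subpop_subset must be nonempty")
    excluded = set(exclude_mirnas)
    sub_catalog = TargetCatalog(
        tuple(p for p in catalog.pairs if p[0] not in excluded)
    )
    return infer_negative_network(
        mirna_matrix, gene_matrix, sub_catalog, list(subpop_subset), alpha=alpha
    )
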