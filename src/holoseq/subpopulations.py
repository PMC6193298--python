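"""Feature scaling, hierarchical clustering, PCA retention, and 2-D
embedding used to define cell subpopulations.

Cells are clustered on scaled feature profiles with agglomerative
clustering (euclidean metric, complete or average linkage); embeddings use
PCA retaining the components that explain a target share of variance (85%
by default) followed by t-SNE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from holoseq.io import ExpressionMatrix


@dataclass
class ClusterResult:
    linkage_tree: np.ndarray  # scipy linkage matrix, n-1 merges
    cell_ids: list[str]
    distance_metric: str
    linkage_method: str

    def labels_at_k(self, k: int) -> dict[str, int]:
        labels = fcluster(self.linkage_tree, t=k, criterion="maxclust")
        return dict(zip(self.cell_ids, (int(x) for x in labels)))


def _as_frame(matrix: Union[ExpressionMatrix, pd.DataFrame]) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def scale_features(
    matrix: Union[ExpressionMatrix, pd.DataFrame], mode: str
) -> pd.DataFrame:
    """Row-wise transforms: ``row_max_divide`` (divide each feature by its
    max), ``zscore`` (mean 0, sample sd 1; zero-variance rows dropped with
    a warning), or ``log2p1``.  Transforms compose by repeated calls."""
    df = _as_frame(matrix).astype(float)
    if mode == "row_max_divide":
        mx = df.max(axis=1)
        if (mx <= 0).any():
            bad = mx.index[mx <= 0][0]
            raise ValueError(f"feature {bad!r}: row max must be > 0")
        return df.div(mx, axis=0)
    if mode == "zscore":
        sd = df.std(axis=1, ddof=1)
        dropped = list(df.index[sd == 0])
        if dropped:
            warnings.warn(f"dropping {len(dropped)} zero-variance features")
            df = df.loc[sd > 0]
            sd = sd[sd > 0]
        return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    if mode == "log2p1":
        return np.log2(df + 1.0)
    raise ValueError(f"unknown scaling mode {mode!r}")


def hierarchical_cluster(
    matrix: Union[ExpressionMatrix, pd.DataFrame],
    metric: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of cells (columns) on their feature
    profiles."""
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 cells to cluster")
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"NaN in matrix at feature {feat!r}")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    X = df.to_numpy(dtype=float).T  # cells as rows
    Z = scipy_linkage(pdist(X, metric=metric), method=linkage)
    return ClusterResult(Z, list(df.columns), metric, linkage)


def pca_retain(
    matrix: Union[ExpressionMatrix, pd.DataFrame],
    variance_fraction: float = 0.85,
) -> np.ndarray:
    """Scores of the smallest set of top principal components whose
    eigenvalues reach ``variance_fraction`` of the total (cells are the
    samples; features are centered)."""
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float).T  # cells x features
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ev = S**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("matrix has rank 0 after centering")
    shares = np.cumsum(ev) / total
    k = int(np.searchsorted(shares, variance_fraction - 1e-12) + 1)
    k = min(k, int((ev > total * 1e-12).sum()))
    return U[:, :k] * S[:k]


def embed_2d(
    scores: np.ndarray, perplexity: float = 6.0, seed: int = 0
) -> np.ndarray:
    """t-SNE embedding of component scores to 2-D (deterministic per seed).

    Requires n_cells > 3 * perplexity."""
    from sklearn.manifold import TSNE

    n = scores.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large: need n_cells > {3 * perplexity:g}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(np.asarray(scores, dtype=float))
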