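"""Cell embedding, m6A-augmented hierarchical clustering, and gene-trend
K-means.

Cells are embedded from z-score-normalized expression (PCA by default —
fully deterministic — or a seeded UMAP), then clustered hierarchically on
the embedding joined with the per-cell m6A level as a third feature, each
column standardized so the heterogeneous components weigh equally.  Stage
trend clustering of genes uses seeded Lloyd K-means with a documented
empty-cluster reseed rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = [
    "ClusterResult",
    "zscore_genes",
    "embed_cells",
    "m6a_augmented_clustering",
    "kmeans_gene_trends",
]


@dataclass
class ClusterResult:
    labels: np.ndarray            # one integer per cell, 0 = largest cluster
    embedding: np.ndarray         # n_cells x 2
    features: np.ndarray          # n_cells x 3 (embedding + m6A level)
    linkage_method: str = "ward"
    seed: int | None = None
    cells: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=["dim1", "dim2", "m6a_level"])
        df["label"] = self.labels
        if self.cells:
            df.index = pd.Index(self.cells, name="cell")
        return df


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across cells; zero-variance genes become 0."""
    vals = matrix.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=matrix.index, columns=matrix.columns)


def embed_cells(matrix: pd.DataFrame, method: str = "pca",
                seed: int = 0) -> np.ndarray:
    """2-D embedding of cells from a genes x cells matrix.

    The matrix is z-scored per gene first.  ``method='pca'`` is fully
    deterministic, with the sign convention that each component's
    largest-magnitude loading is positive; an all-constant matrix maps every
    cell to the origin.  ``method='umap'`` requires umap-learn and is
    deterministic under a fixed seed.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 cells to embed")
    z = zscore_genes(matrix).to_numpy(float).T  # cells x genes
    if method == "pca":
        if not z.any():
            return np.zeros((z.shape[0], 2))
        n_comp = min(2, min(z.shape) - 0)
        pca = PCA(n_components=n_comp, svd_solver="full")
        emb = pca.fit_transform(z)
        for j in range(emb.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                emb[:, j] *= -1
        if emb.shape[1] < 2:
            emb = np.column_stack([emb, np.zeros(len(emb))])
        return emb
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed)
        return reducer.fit_transform(z)
    raise ValueError(f"unknown embedding method {method!r}")


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    out = x.astype(float).copy()
    sd = out.std(axis=0, ddof=0)
    mu = out.mean(axis=0)
    nz = sd > 0
    out[:, nz] = (out[:, nz] - mu[nz]) / sd[nz]
    return out


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw labels to 0,1,... by decreasing cluster size (stable ties)."""
    uniq, counts = np.unique(raw, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.array([mapping[v] for v in raw])


def m6a_augmented_clustering(
    embedding: np.ndarray,
    m6a_levels: np.ndarray | pd.Series,
    k: int | None = None,
    cut_height: float | None = None,
    standardize: bool = True,
    linkage_method: str = "ward",
    cells: list[str] | None = None,
) -> ClusterResult:
    """Hierarchical clustering of cells on (embedding, m6A level).

    The two embedding coordinates and the m6A level form a 3-column feature
    block; with ``standardize`` each column is scaled to unit variance so
    the level competes on equal footing with the embedding.  Agglomeration
    is Ward on Euclidean distances; the tree is cut at ``k`` clusters or at
    ``cut_height``.  Labels are relabeled by decreasing cluster size.
    """
    emb = np.asarray(embedding, float)
    levels = np.asarray(m6a_levels, float)
    if emb.ndim != 2 or emb.shape[1] != 2:
        raise ValueError("embedding must be n_cells x 2")
    if len(levels) != len(emb):
        raise ValueError("one m6A level per cell required")
    if np.isnan(levels).any():
        raise ValueError("undefined m6A levels must be excluded before clustering")
    if k is not None and k > len(emb):
        raise ValueError(f"k={k} exceeds number of cells {len(emb)}")
    if (k is None) == (cut_height is None):
        raise ValueError("specify exactly one of k and cut_height")
    feats = np.column_stack([emb, levels])
    x = _standardize_columns(feats) if standardize else feats
    if k == 1:
        labels = np.zeros(len(x), dtype=int)
    else:
        tree = linkage(x, method=linkage_method)
        if k is not None:
            raw = fcluster(tree, t=k, criterion="maxclust")
        else:
            raw = fcluster(tree, t=cut_height, criterion="distance")
        labels = _relabel_by_size(raw)
    return ClusterResult(labels=labels, embedding=emb, features=feats,
                         linkage_method=linkage_method, cells=cells or [])


def kmeans_gene_trends(
    stage_matrix: pd.DataFrame,
    k: int,
    max_iterations: int = 10_000,
    seed: int = 0,
    return_inertia: bool = False,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd K-means of per-gene stage trends (rows already z-scored).

    Initialization picks ``k`` distinct rows with a seeded generator.  An
    iteration that empties a cluster reseeds that centroid from the point
    farthest from its assigned centroid.  Stops at assignment convergence or
    ``max_iterations``; the within-cluster sum of squares is non-increasing
    across iterations.  Returns (labels, centroids).
    """
    x = stage_matrix.to_numpy(float)
    n, d = x.shape
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes {n}")
    if d < 2:
        raise ValueError("need at least 2 stages")
    rng = np.random.default_rng(seed)
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    inertia: list[float] = []
    for _ in range(max_iterations):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia.append(float(d2[np.arange(n), new_labels].sum()))
        for j in range(k):
            members = new_labels == j
            if members.any():
                centroids[j] = x[members].mean(axis=0)
            else:
                # reseed an emptied centroid from the farthest point
                far = d2[np.arange(n), new_labels].argmax()
                centroids[j] = x[far]
                new_labels[far] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
    if return_inertia:
        return labels, centroids, inertia
    return labels, centroids
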