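"""Normalization, per-modality embeddings, joint embedding and graph clustering.

RNA is log-normalized and embedded by PCA on (optionally scaled) genes; ATAC
is embedded by TF-IDF followed by truncated SVD (latent semantic indexing),
whose first component typically tracks sequencing depth and is dropped by
convention (dims 2..n). The joint embedding z-scores each modality's
coordinates and concatenates them with sqrt-weight scaling — a deliberately
simple stand-in for weighted-nearest-neighbor integration that preserves the
pipeline's clustering logic. Clustering is Leiden community detection on a
shared-nearest-neighbor graph.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors


@dataclass
class Embedding:
    cells: pd.Index
    coords: np.ndarray              # cell x dim
    modality: str                   # rna | atac | joint
    dims_used: list = field(default_factory=list)
    depth_correlation: np.ndarray | None = None   # |corr| of each dim with depth

    def __post_init__(self):
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite values")
        if self.coords.shape[1] < 2:
            raise ValueError("embedding must have at least 2 dimensions")

    def selected(self) -> np.ndarray:
        """Coordinates restricted to ``dims_used`` (all dims when unset)."""
        if not len(self.dims_used):
            return self.coords
        return self.coords[:, list(self.dims_used)]


@dataclass
class Clustering:
    labels: pd.Series               # cell -> dense cluster id starting at 0
    resolution: float
    modality: str
    k_neighbors: int = 20
    seed: int = 0
    method: str = "leiden-snn"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def lognormalize(counts, scale_factor: float = 1e4) -> sp.csr_matrix:
    """x' = ln(1 + scale_factor * x / column_sum), feature x cell."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(counts)
    colsum = np.asarray(X.sum(axis=0)).ravel().astype(float)
    if (colsum == 0).any():
        raise ValueError("all-zero cell encountered; run QC filtering first")
    X = X.astype(float)
    X = X.multiply(sp.csr_matrix(scale_factor / colsum))
    X = X.tocsr()
    X.data = np.log1p(X.data)
    return X.tocsr()


def _fix_signs(coords: np.ndarray, components: np.ndarray):
    """Deterministic sign convention: the largest-|loading| entry is positive."""
    for d in range(components.shape[0]):
        j = np.argmax(np.abs(components[d]))
        if components[d, j] < 0:
            components[d] *= -1
            coords[:, d] *= -1


def tfidf_transform(atac_counts, scale_factor: float = 1e4) -> sp.csr_matrix:
    """log1p(scale_factor * TF * IDF) with TF = count/cell depth and
    IDF = n_cells / peak document frequency. Zero-count peaks are excluded
    (their IDF is undefined)."""
    X = atac_counts.tocsr() if sp.issparse(atac_counts) else sp.csr_matrix(atac_counts)
    n_cells = X.shape[1]
    rowsum = np.asarray(X.sum(axis=1)).ravel()
    X = X[rowsum > 0]
    depth = np.asarray(X.sum(axis=0)).ravel().astype(float)
    tf = X.multiply(sp.csr_matrix(1.0 / depth)).tocsr()
    df = np.asarray((X > 0).sum(axis=1)).ravel().astype(float)
    idf = n_cells / df
    vals = tf.multiply(sp.csr_matrix(idf[:, None])).tocsr()
    vals.data = np.log1p(scale_factor * vals.data)
    return vals


def tfidf_lsi(atac_counts, cells: pd.Index, n_dims: int = 30,
              scale_factor: float = 1e4, drop_first: bool = True) -> Embedding:
    """TF-IDF transform + truncated SVD of the peak x cell matrix.

    Zero-count peaks are excluded before the IDF. ``dims_used`` defaults to
    2..n_dims because component 1 correlates with per-cell depth; the
    per-dimension |correlation| with depth is reported so callers can choose
    differently.
    """
    X = atac_counts.tocsr() if sp.issparse(atac_counts) else sp.csr_matrix(atac_counts)
    n_peaks, n_cells = X.shape
    if n_dims >= min(n_peaks, n_cells):
        raise ValueError("n_dims must be smaller than both matrix dimensions")
    depth = np.asarray(X.sum(axis=0)).ravel().astype(float)
    vals = tfidf_transform(X, scale_factor)
    svd = TruncatedSVD(n_components=n_dims, algorithm="arpack", random_state=0)
    coords = svd.fit_transform(vals.T.tocsr())
    comp = svd.components_.copy()
    _fix_signs(coords, comp)
    depth_corr = np.array([
        abs(np.corrcoef(coords[:, d], depth)[0, 1])
        if coords[:, d].std() > 0 and depth.std() > 0 else 0.0
        for d in range(n_dims)])
    dims = list(range(1, n_dims)) if drop_first else list(range(n_dims))
    return Embedding(cells=pd.Index(cells), coords=coords, modality="atac",
                     dims_used=dims, depth_correlation=depth_corr)


def pca_embed(normalized_rna, cells: pd.Index, n_dims: int = 18,
              scale: bool = True) -> Embedding:
    """PCA of cells on centered (and optionally unit-scaled) genes."""
    X = normalized_rna.toarray() if sp.issparse(normalized_rna) else np.asarray(normalized_rna)
    X = X.T.astype(float)                     # cell x gene
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    rank = min(X.shape)
    if n_dims > rank:
        raise ValueError(f"n_dims={n_dims} exceeds the matrix rank bound {rank}")
    pca = PCA(n_components=n_dims, svd_solver="full")
    coords = pca.fit_transform(X)
    comp = pca.components_.copy()
    _fix_signs(coords, comp)
    return Embedding(cells=pd.Index(cells), coords=coords, modality="rna",
                     dims_used=list(range(n_dims)))


def joint_embedding(rna_emb: Embedding, atac_emb: Embedding,
                    weight_rna: float = 0.5) -> Embedding:
    """Concatenate block-normalized embeddings with sqrt-weight scaling.

    Each modality's coordinate block is centered and divided by its total
    standard deviation (the square root of the summed per-dimension
    variances), so the two modalities contribute comparably while the
    within-modality variance ordering of the components — which carries the
    biological signal — is preserved. Per-dimension standardization would
    instead give noise components the same weight as the leading ones.
    """
    if not (0 <= weight_rna <= 1):
        raise ValueError("weight_rna must lie in [0, 1]")
    if list(rna_emb.cells) != list(atac_emb.cells):
        raise ValueError("cell order differs between the two embeddings")

    def block_norm(A):
        A = np.asarray(A, dtype=float)
        A = A - A.mean(axis=0)
        total_sd = np.sqrt(A.var(axis=0).sum())
        return A / (total_sd if total_sd > 0 else 1.0)

    a = block_norm(rna_emb.selected()) * np.sqrt(weight_rna)
    b = block_norm(atac_emb.selected()) * np.sqrt(1.0 - weight_rna)
    parts = []
    if weight_rna > 0:
        parts.append(a)
    if weight_rna < 1:
        parts.append(b)
    coords = np.hstack(parts)
    return Embedding(cells=rna_emb.cells, coords=coords, modality="joint",
                     dims_used=list(range(coords.shape[1])))


def snn_graph(coords: np.ndarray, k_neighbors: int = 20,
              prune: float = 1.0 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets (self included),
    pruned below ``prune``."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    knn = nn.kneighbors_graph(coords, mode="connectivity")
    knn = knn.maximum(sp.identity(n, format="csr"))
    k = knn.sum(axis=1).A.ravel() if hasattr(knn.sum(axis=1), "A") else \
        np.asarray(knn.sum(axis=1)).ravel()
    inter = (knn @ knn.T).tocoo()
    union = k[inter.row] + k[inter.col] - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    return sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))


def cluster_graph(embedding: Embedding, k_neighbors: int = 20,
                  resolution: float = 0.3, seed: int = 0) -> Clustering:
    """Leiden clustering (RB-configuration modularity) of the SNN graph."""
    coords = embedding.selected()
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    adj = snn_graph(coords, k_neighbors=k_neighbors)
    adj = adj.maximum(adj.T).tocoo()
    mask = adj.row < adj.col
    g = ig.Graph(n=n, edges=list(zip(adj.row[mask], adj.col[mask])),
                 edge_attrs={"weight": adj.data[mask]})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership)
    order = np.argsort(-np.bincount(labels), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[labels]
    return Clustering(labels=pd.Series(labels, index=embedding.cells, name="cluster"),
                      resolution=resolution, modality=embedding.modality,
                      k_neighbors=k_neighbors, seed=seed)


def composition_table(clustering: Clustering, cell_meta: pd.DataFrame,
                      group_cols=("sex", "stage")) -> pd.DataFrame:
    """Percentage of each group's cells falling in each cluster (rows sum to 100)."""
    meta = cell_meta.loc[clustering.labels.index]
    groups = meta[list(group_cols)].astype(str).agg("_".join, axis=1)
    tab = pd.crosstab(groups, clustering.labels)
    totals = tab.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"empty groups: {list(tab.index[empty])}")
        totals[empty] = 1
    return tab.div(totals, axis=0) * 100.0
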