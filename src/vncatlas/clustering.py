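"""Linear embedding and seeded graph clustering.

PCA (full SVD, deterministic sign convention) on the scaled HVG submatrix,
a k-nearest-neighbour graph in PC space, and Leiden community detection at
a configurable resolution. Labels are relabelled to consecutive integers in
descending cluster-size order, so the largest cluster is always 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import ExpressionDataset

__all__ = ["ClusteringConfig", "embed_and_cluster", "cluster_summary", "remove_clusters"]


@dataclass
class ClusteringConfig:
    """Embedding/clustering knobs. The study's two passes used 35 PCs at
    resolution 0.8 (initial) and 33 PCs at resolution 1.5 (filtered)."""

    n_hvg: int = 2000
    n_pcs: int = 35
    resolution: float = 0.8
    n_neighbors: int = 20
    seed: int = 0
    algorithm: str = "leiden"  # or "louvain"
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.algorithm not in ("leiden", "louvain"):
            raise ValueError("algorithm must be 'leiden' or 'louvain'")


def _pca(X: np.ndarray, n_pcs: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    max_rank = min(X.shape) - (1 if X.shape[0] > 1 else 0)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds matrix rank bound {max_rank}; reduced", stacklevel=3)
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(X)
    return emb, pca.explained_variance_ratio_


def knn_graph(embedding: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Undirected unweighted union k-NN graph (self excluded)."""
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, embedding.shape[0]))
    nn.fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=embedding.shape[0], edges=sorted(edges), directed=False)
    return g


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Consecutive integer labels ordered by descending cluster size; ties
    broken by the original label for determinism."""
    labels, counts = np.unique(membership, return_counts=True)
    order = labels[np.lexsort((labels, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.asarray([mapping[m] for m in membership], dtype=int)


def embed_and_cluster(
    ds: ExpressionDataset,
    genes: np.ndarray | None = None,
    config: ClusteringConfig | None = None,
) -> np.ndarray:
    """Cluster cells; labels are stored in ``cell_meta["cluster"]``.

    ``genes`` are the HVG column indices used for the embedding (all genes
    if omitted). The PC embedding is stored under ``embeddings["pca"]`` and
    the explained-variance ratio is logged to provenance. Identical seed and
    input give identical labels.
    """
    cfg = config or ClusteringConfig()
    if "scaled" not in ds.layers:
        raise ValueError("run scale() first")
    cols = np.arange(ds.n_genes) if genes is None else np.asarray(genes, dtype=int)
    X = np.asarray(ds.layers["scaled"])[:, cols]
    emb, evr = _pca(X, cfg.n_pcs, cfg.seed)
    ds.embeddings["pca"] = emb
    g = knn_graph(emb, cfg.n_neighbors)
    if cfg.algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=cfg.resolution,
            seed=cfg.seed,
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    else:
        import random

        random.seed(cfg.seed)
        membership = np.asarray(
            g.community_multilevel(resolution=cfg.resolution).membership
        )
    labels = _relabel_by_size(membership)
    ds.cell_meta["cluster"] = labels
    ds.log_op(
        "embed_and_cluster",
        n_pcs=int(emb.shape[1]),
        resolution=cfg.resolution,
        algorithm=cfg.algorithm,
        seed=cfg.seed,
        n_clusters=int(labels.max() + 1),
        explained_variance=float(np.sum(evr)),
    )
    return labels


def cluster_summary(
    ds: ExpressionDataset,
    clusters: np.ndarray | None = None,
    marker_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster mean UMI/gene counts, size, and mean lognorm of marker
    genes — the evidence table for the user's manual removal of
    heterogeneous/non-neuronal clusters."""
    labels = np.asarray(
        ds.cell_meta["cluster"] if clusters is None else clusters
    )
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    ngene = np.asarray((ds.counts > 0).sum(axis=1)).ravel()
    rows = []
    for c in np.unique(labels):
        m = labels == c
        row = {
            "cluster": int(c),
            "n_cells": int(m.sum()),
            "mean_numi": float(totals[m].mean()),
            "mean_ngene": float(ngene[m].mean()),
        }
        for gene in marker_genes or []:
            vec = ds.gene_vector(gene, layer="lognorm" if "lognorm" in ds.layers else None)
            row[f"mean_{gene}"] = float(vec[m].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def remove_clusters(
    ds: ExpressionDataset, remove: list[int], clusters: np.ndarray | None = None
) -> ExpressionDataset:
    """Drop the listed clusters (an explicit user decision, not automated)."""
    labels = np.asarray(ds.cell_meta["cluster"] if clusters is None else clusters)
    keep = ~np.isin(labels, list(remove))
    out = ds.subset_cells(keep)
    out.log_op("remove_clusters", removed=list(map(int, remove)))
    return out
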