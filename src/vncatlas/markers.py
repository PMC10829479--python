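"""Cluster marker detection by Wilcoxon rank-sum on log-normalized values.

Per cluster, genes first pass two pre-filters — detected in at least half
the cluster's cells (min_pct 0.5) and log2 fold-change of at least 0.32
(about 1.25-fold), positive markers only — and then a two-sided rank-sum
test of cluster vs all other cells, Bonferroni-adjusted over the genes
tested in that cluster. The fold change is
log2((mean(expm1(lognorm))_in + 1) / (mean(expm1(lognorm))_out + 1)),
the convention behind "avg_log2FC" columns in Seurat-style marker tables.

The rank-sum p-value is exact (conditional permutation distribution of the
mid-rank sum, computed by dynamic programming, so ties are handled exactly)
for small comparisons, and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .datamodel import ExpressionDataset

__all__ = ["wilcoxon_rank_sum", "find_all_markers", "top_markers"]

#: exact DP is used when the pooled sample is at most this large
_EXACT_MAX_N = 30


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, w2_obs: int) -> float:
    """Two-sided exact p for the rank-sum statistic under permutation.

    ``ranks2`` are doubled mid-ranks (integers) of the pooled sample;
    ``w2_obs`` the doubled rank-sum of group 1. p = min(1, 2 * min(lower,
    upper tail)), observed value included in both tails.
    """
    max_sum = int(ranks2.sum())
    # f[j, s] = number of j-subsets with doubled-rank-sum s
    f = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(n1, 0, -1):
            f[j, r:] += f[j - 1, : max_sum + 1 - r]
    total = comb(len(ranks2), n1)
    dist = f[n1]
    lower = dist[: w2_obs + 1].sum() / total
    upper = dist[w2_obs:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value for samples x vs y.

    Exact by enumeration (tie-aware) when the pooled size is small;
    otherwise normal approximation with tie correction, no continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    if n <= _EXACT_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        return _exact_rank_sum_p(ranks2, n1, int(round(2 * w)))
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all values identical
        return 1.0
    z = (w - mean_w) / sqrt(var_w)
    return erfc(abs(z) / sqrt(2.0))


def _dense(mat) -> np.ndarray:
    return np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)


def find_all_markers(
    ds: ExpressionDataset,
    clusters: np.ndarray | None = None,
    min_pct: float = 0.5,
    lfc_threshold: float = 0.32,
    only_pos: bool = True,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Marker table over all clusters (columns: gene, cluster, avg_log2FC,
    pct1, pct2, p_value, p_adjusted).

    Clusters smaller than ``min_cluster_size`` are skipped with a warning.
    The Bonferroni factor is the number of genes tested (i.e. passing the
    pre-filters) in that cluster.
    """
    if "lognorm" not in ds.layers:
        raise ValueError("run log_normalize first")
    labels = np.asarray(ds.cell_meta["cluster"] if clusters is None else clusters)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    ln = _dense(ds.layers["lognorm"])
    detected = ln > 0
    expm1 = np.expm1(ln)
    rows = []
    for c in np.unique(labels):
        in_mask = labels == c
        n_in = int(in_mask.sum())
        if n_in < min_cluster_size:
            warnings.warn(f"cluster {c} has {n_in} < {min_cluster_size} cells; skipped", stacklevel=2)
            continue
        out_mask = ~in_mask
        pct1 = detected[in_mask].mean(axis=0)
        pct2 = detected[out_mask].mean(axis=0)
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[out_mask].mean(axis=0)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        passing = pct1 >= min_pct
        passing &= (lfc >= lfc_threshold) if only_pos else (np.abs(lfc) >= lfc_threshold)
        test_idx = np.where(passing)[0]
        m = len(test_idx)
        for j in test_idx:
            p = wilcoxon_rank_sum(ln[in_mask, j], ln[out_mask, j])
            rows.append(
                {
                    "gene": ds.gene_ids[j],
                    "cluster": int(c),
                    "avg_log2FC": float(lfc[j]),
                    "pct1": float(pct1[j]),
                    "pct2": float(pct2[j]),
                    "p_value": float(p),
                    "p_adjusted": float(min(1.0, p * m)),
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "cluster", "avg_log2FC", "pct1", "pct2", "p_value", "p_adjusted"]
    )
    return table.sort_values(["cluster", "p_value", "gene"], kind="stable").reset_index(drop=True)


def top_markers(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-cluster top-k markers by avg_log2FC; ties broken by gene id."""
    ordered = table.sort_values(
        ["cluster", "avg_log2FC", "gene"], ascending=[True, False, True], kind="stable"
    )
    return ordered.groupby("cluster", group_keys=False).head(k).reset_index(drop=True)
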