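"""Markov diffusion imputation and gene-gene correlation ranking.

The diffusion operator is built MAGIC-style: an adaptive Gaussian kernel on
k-nearest-neighbour distances in PC space (per-cell bandwidth = distance to
the k-th neighbour, decay exponent alpha), symmetrized as (A + A^T)/2 and
row-normalized into a stochastic matrix P. Imputed expression is P^t applied
to the lognorm layer; t = 0 is the identity. Correlation ranking then orders
every gene by |cor| with a chosen target gene (the serotonin-transporter
style co-expression screen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .datamodel import ExpressionDataset

__all__ = ["DiffusionOperator", "build_diffusion_operator", "impute", "correlate_with_gene"]


@dataclass
class DiffusionOperator:
    """Row-stochastic cells x cells transition matrix with its parameters."""

    matrix: np.ndarray
    k: int
    alpha: float

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("operator must be square")
        if (P < 0).any():
            raise ValueError("operator entries must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("operator rows must sum to 1")
        self.matrix = P

    def power(self, t: int) -> np.ndarray:
        """P^t by repeated multiplication (t = 0 gives the identity)."""
        if t < 0:
            raise ValueError("diffusion time t must be >= 0")
        out = np.eye(self.matrix.shape[0])
        base = self.matrix.copy()
        n = t
        while n:  # exponentiation by squaring; exact for integer t
            if n & 1:
                out = out @ base
            base = base @ base
            n >>= 1
        return out

    def apply(self, X: np.ndarray, t: int) -> np.ndarray:
        return self.power(t) @ np.asarray(X)


def build_diffusion_operator(
    embedding: np.ndarray, k: int = 5, alpha: float = 1.0
) -> DiffusionOperator:
    """Adaptive-kernel diffusion operator from a cells x dims embedding.

    Affinity a_ij = exp(-(d_ij / sigma_i)^alpha) with sigma_i the distance
    from cell i to its k-th nearest neighbour (self excluded). Cells with
    sigma_i = 0 (exact duplicates) take affinity 1 at distance 0 and 0
    elsewhere. The kernel is symmetrized then row-normalized.
    """
    X = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    D = cdist(X, X)
    sigma = np.sort(D, axis=1)[:, k]  # k-th neighbour excluding self (column 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(D == 0, 0.0, np.where(sigma[:, None] > 0, D / sigma[:, None], np.inf))
    A = np.exp(-(scaled**alpha))
    A = (A + A.T) / 2.0
    P = A / A.sum(axis=1, keepdims=True)
    return DiffusionOperator(matrix=P, k=k, alpha=alpha)


def impute(ds: ExpressionDataset, operator: DiffusionOperator, t: int = 3) -> ExpressionDataset:
    """Store the "imputed" layer = P^t @ lognorm; t=0 reproduces lognorm."""
    if "lognorm" not in ds.layers:
        raise ValueError("run log_normalize first")
    if t < 0:
        raise ValueError("diffusion time t must be >= 0")
    ln = ds.layers["lognorm"]
    ln = np.asarray(ln.todense()) if sp.issparse(ln) else np.asarray(ln)
    ds.layers["imputed"] = operator.apply(ln, t)
    ds.log_op("impute", k=operator.k, alpha=operator.alpha, t=t)
    return ds


def correlate_with_gene(
    ds: ExpressionDataset,
    target_gene: str,
    layer: str = "imputed",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of every gene with ``target_gene`` on the given layer.

    Returns a frame with columns gene, cor, abs_cor, rank, zero_variance,
    sorted by abs_cor descending (ties broken by gene id). Zero-variance
    genes get cor = 0 and are flagged. The target correlates 1 with itself.
    """
    if layer not in ds.layers:
        raise ValueError(f"layer {layer!r} not computed")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = ds.layers[layer]
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    (tj,), _ = ds.resolve_genes([target_gene])
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    target = X[:, tj]
    Xc = X - X.mean(axis=0)
    tc = target - target.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    zero_var = sx == 0
    if st == 0:
        cor = np.zeros(X.shape[1])
        zero_var = np.ones(X.shape[1], dtype=bool)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = np.where(zero_var, 0.0, (Xc * tc[:, None]).sum(axis=0) / np.where(zero_var, 1.0, sx) / st)
    cor = np.clip(cor, -1.0, 1.0)
    out = pd.DataFrame(
        {"gene": ds.gene_ids, "cor": cor, "abs_cor": np.abs(cor), "zero_variance": zero_var}
    )
    out = out.sort_values(["abs_cor", "gene"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
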