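"""Normalization, variable-feature selection and per-gene scaling.

log_normalize:  x' = ln(1 + scale_factor * x / cell_total), scale_factor 1e4.
select_hvg:     variance-stabilizing ranking — a loess trend of log10
                variance on log10 mean predicts each gene's expected
                standard deviation; counts are standardized against it,
                clipped at sqrt(n_cells), and genes are ranked by the
                variance of the clipped values.
scale:          per-gene z-score of lognorm across cells using the
                population (1/n) standard deviation; constant genes map to
                all zeros.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm

from .datamodel import ExpressionDataset

__all__ = ["log_normalize", "select_hvg", "scale"]


def log_normalize(ds: ExpressionDataset, scale_factor: float = 1e4) -> ExpressionDataset:
    """Store the "lognorm" layer; zero counts stay exactly zero."""
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = ds.cell_ids[totals == 0][:5]
        raise ValueError(f"cells with zero total counts (run QC first): {list(bad)}")
    norm = ds.counts.multiply(scale_factor / totals[:, None]).log1p()
    ds.layers["lognorm"] = sp.csr_matrix(norm)
    ds.log_op("log_normalize", scale_factor=scale_factor)
    return ds


def _clipped_standardized_variance(
    counts: sp.spmatrix, mean: np.ndarray, sd_pred: np.ndarray
) -> np.ndarray:
    """Variance of z = clip((x - mu)/sd, max=sqrt(n)) per gene, computed on
    sparse counts without densifying (zeros contribute (0-mu)/sd terms)."""
    n = counts.shape[0]
    clip = np.sqrt(n)
    ok = sd_pred > 0
    var_std = np.zeros(counts.shape[1])
    csc = counts.tocsc()
    for j in np.where(ok)[0]:
        x = csc.data[csc.indptr[j] : csc.indptr[j + 1]]
        z_nz = np.clip((x - mean[j]) / sd_pred[j], -clip, clip)
        z_zero = np.clip(-mean[j] / sd_pred[j], -clip, clip)
        n_zero = n - x.size
        s1 = z_nz.sum() + n_zero * z_zero
        s2 = (z_nz**2).sum() + n_zero * z_zero**2
        # sample variance (n-1), matching the vst convention
        var_std[j] = (s2 - s1**2 / n) / (n - 1)
    return var_std


def select_hvg(ds: ExpressionDataset, n: int = 2000, loess_frac: float = 0.3) -> np.ndarray:
    """Return indices of the top-``n`` variable genes, ranked; deterministic.

    Constant genes have standardized variance 0 and rank last; if ``n``
    meets or exceeds the gene count, all genes are returned in rank order.
    """
    counts = ds.counts
    ncells = counts.shape[0]
    if ncells < 2:
        raise ValueError("need at least 2 cells for variance ranking")
    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = np.asarray(counts.power(2).mean(axis=0)).ravel()
    var = (sq - mean**2) * ncells / (ncells - 1)

    sd_pred = np.zeros_like(mean)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 3:
        x = np.log10(mean[fit_mask])
        y = np.log10(var[fit_mask])
        fitted = sm.nonparametric.lowess(
            y, x, frac=loess_frac, return_sorted=False
        )
        sd_pred[fit_mask] = np.sqrt(10.0**fitted)
    else:  # too few informative genes for a trend: fall back to raw sd
        sd_pred[fit_mask] = np.sqrt(var[fit_mask])

    var_std = _clipped_standardized_variance(counts, mean, sd_pred)
    # rank by standardized variance, ties broken by gene id for determinism
    order = np.lexsort((ds.gene_ids, -var_std))
    k = min(n, ds.n_genes)
    hvg = order[:k]
    ds.log_op("select_hvg", n=int(k))
    return hvg


def scale(
    ds: ExpressionDataset,
    genes: np.ndarray | None = None,
    max_value: float | None = None,
) -> ExpressionDataset:
    """Store the dense "scaled" layer (z-scores of lognorm per gene).

    ``genes`` restricts which columns get non-zero scaled values (others are
    left at zero); the layer always has the full matrix shape. ``max_value``
    optionally clips the scaled values symmetrically.
    """
    if "lognorm" not in ds.layers:
        raise ValueError("run log_normalize first")
    ln = ds.layers["lognorm"]
    cols = np.arange(ds.n_genes) if genes is None else np.asarray(genes, dtype=int)
    X = np.asarray(ln[:, cols].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (1/n) convention
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if max_value is not None:
        Z = np.clip(Z, -max_value, max_value)
    scaled = np.zeros(ds.counts.shape)
    scaled[:, cols] = Z
    ds.layers["scaled"] = scaled
    ds.log_op("scale", n_genes=int(cols.size), max_value=max_value)
    return ds
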