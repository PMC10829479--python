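"""Cell- and gene-level quality filters.

Cells are removed when they have fewer than 500 expressed genes, fewer than
1000 UMIs, a log(genes)/log(UMIs) ratio below 0.8, more than 18% of counts
in mitochondrial genes, a ribosomal proportion outside 5-40%, or more than
5% of counts in heat-shock genes. Genes with total counts below 5 or
expressed in fewer than 2 cells are removed afterwards. All removal rules
are strict inequalities, so the keep-side boundary is inclusive (a cell at
exactly 18% mitochondrial counts is kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, GeneSetCatalog

__all__ = [
    "QCThresholds",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "apply_qc",
    "QCFilterResult",
]


@dataclass(frozen=True)
class QCThresholds:
    """Keep-side thresholds; defaults follow the study's stated filters."""

    min_genes: int = 500
    min_umi: int = 1000
    min_log_ratio: float = 0.8
    max_pct_mito: float = 18.0
    min_pct_ribo: float = 5.0
    max_pct_ribo: float = 40.0
    max_pct_hs: float = 5.0
    gene_min_total: int = 5
    gene_min_cells: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"threshold {f.name} must be finite")
        if self.min_pct_ribo >= self.max_pct_ribo:
            raise ValueError("min_pct_ribo must be < max_pct_ribo")


def _family_pct(ds: ExpressionDataset, genes: list[str], totals: np.ndarray, name: str) -> np.ndarray:
    idx, unresolved = ds.resolve_genes(genes, missing="report")
    if unresolved:
        warnings.warn(f"{name} family: {len(unresolved)} genes unresolved: {unresolved}", stacklevel=3)
    if idx.size == 0:
        warnings.warn(f"{name} family resolved no genes; pct set to 0", stacklevel=3)
        return np.zeros(ds.n_cells)
    fam = np.asarray(ds.counts[:, idx].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * fam / totals, 0.0)
    return pct


def compute_qc_metrics(ds: ExpressionDataset, catalog: GeneSetCatalog) -> pd.DataFrame:
    """Per-cell QC metrics table indexed by cell id.

    ``log_ratio`` = log(n_gene)/log(n_umi); it is NaN (undefined) for cells
    with n_umi <= 1. The logarithm base cancels, so any base gives the same
    ratio.
    """
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    n_gene = np.asarray((ds.counts > 0).sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        log_ratio = np.where(
            totals > 1, np.log(np.maximum(n_gene, 1)) / np.log(np.maximum(totals, 2)), np.nan
        )
    fams = catalog.families
    metrics = pd.DataFrame(
        {
            "n_umi": totals.astype(int),
            "n_gene": n_gene.astype(int),
            "log_ratio": log_ratio,
            "pct_mito": _family_pct(ds, fams["mito"], totals, "mito"),
            "pct_ribo": _family_pct(ds, fams["ribo"], totals, "ribo"),
            "pct_hs": _family_pct(ds, fams["heat_shock"], totals, "heat_shock"),
        },
        index=pd.Index(ds.cell_ids, name="cell_id"),
    )
    return metrics


#: rule name -> (metrics column, predicate returning True when VIOLATED)
_CELL_RULES: dict[str, tuple[str, Callable[[np.ndarray, QCThresholds], np.ndarray]]] = {
    "min_genes": ("n_gene", lambda v, t: v < t.min_genes),
    "min_umi": ("n_umi", lambda v, t: v < t.min_umi),
    "min_log_ratio": ("log_ratio", lambda v, t: ~(v >= t.min_log_ratio)),  # NaN violates
    "max_pct_mito": ("pct_mito", lambda v, t: v > t.max_pct_mito),
    "min_pct_ribo": ("pct_ribo", lambda v, t: v < t.min_pct_ribo),
    "max_pct_ribo": ("pct_ribo", lambda v, t: v > t.max_pct_ribo),
    "max_pct_hs": ("pct_hs", lambda v, t: v > t.max_pct_hs),
}


@dataclass
class QCFilterResult:
    """Keep mask plus the attribution of every removed cell to the rules it
    violates (a cell can violate several)."""

    keep: np.ndarray
    violations: pd.DataFrame  # boolean, cells x rules
    rule_counts: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.rule_counts = self.violations.sum(axis=0)

    def report(self, metrics: pd.DataFrame) -> pd.DataFrame:
        """QC report: metrics, kept flag, and semicolon-joined violated rules."""
        rules = self.violations.apply(
            lambda row: ";".join(self.violations.columns[row.to_numpy(dtype=bool)]), axis=1
        )
        out = metrics.copy()
        out["kept"] = self.keep
        out["violated_rules"] = rules
        return out


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> QCFilterResult:
    """Boolean keep-mask over cells; all seven rules must hold to keep."""
    t = thresholds or QCThresholds()
    viol = pd.DataFrame(index=metrics.index)
    for rule, (col, pred) in _CELL_RULES.items():
        viol[rule] = pred(metrics[col].to_numpy(), t)
    keep = ~viol.any(axis=1).to_numpy()
    return QCFilterResult(keep=keep, violations=viol)


def filter_genes(ds: ExpressionDataset, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Keep genes with total count >= gene_min_total detected in >=
    gene_min_cells cells."""
    t = thresholds or QCThresholds()
    totals = np.asarray(ds.counts.sum(axis=0)).ravel()
    n_cells_expr = np.asarray((ds.counts > 0).sum(axis=0)).ravel()
    return (totals >= t.gene_min_total) & (n_cells_expr >= t.gene_min_cells)


def apply_qc(
    ds: ExpressionDataset,
    catalog: GeneSetCatalog,
    thresholds: QCThresholds | None = None,
    doublet_hook: Callable[[ExpressionDataset], np.ndarray] | None = None,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Run the full QC sequence: cell filters, then gene filters, then the
    doublet hook (default: identity).

    Cell metrics are computed once on the incoming gene set and not
    recomputed after gene filtering, mirroring the stated pipeline order.
    The doublet hook receives the filtered dataset and returns a keep-mask;
    the default keeps everything, standing in for an external doublet caller.

    Returns the filtered dataset and the per-cell QC report.
    """
    t = thresholds or QCThresholds()
    metrics = compute_qc_metrics(ds, catalog)
    cell_res = filter_cells(metrics, t)
    report = cell_res.report(metrics)
    out = ds.subset_cells(cell_res.keep)
    gene_keep = filter_genes(out, t)
    out = out.subset_genes(gene_keep)
    if doublet_hook is not None:
        doublet_keep = np.asarray(doublet_hook(out), dtype=bool)
        out = out.subset_cells(doublet_keep)
    out.log_op(
        "apply_qc",
        thresholds=t.__dict__,
        cells_removed=int((~cell_res.keep).sum()),
        genes_removed=int((~gene_keep).sum()),
    )
    return out, report
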