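"""Cell-cycle phase scoring and phase-composition statistics.

Phase scores are module scores: the mean lognorm of the phase gene set
minus the mean lognorm of control genes drawn from expression-matched bins
(for each set gene, ``n_ctrl`` control genes are sampled with replacement
from the bin containing that gene). Cells with both the S and G2/M scores
at or below zero are assigned G1 — the "no detectable cycling programme"
default; otherwise the larger score wins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2_contingency

from .datamodel import ExpressionDataset

__all__ = [
    "score_gene_set",
    "assign_phase",
    "score_cell_cycle",
    "phase_composition_test",
    "PhaseCompositionResult",
]

PHASES = ("G1", "S", "G2M")


def score_gene_set(
    ds: ExpressionDataset,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Module score per cell for ``gene_set``; deterministic given ``seed``.

    Genes are ordered by their mean lognorm across cells and split into
    ``n_bins`` equal-size bins; the control pool pools ``n_ctrl`` draws (with
    replacement, set genes not excluded) per set gene from the matching bin.
    """
    if "lognorm" not in ds.layers:
        raise ValueError("run log_normalize first")
    idx, unresolved = ds.resolve_genes(gene_set, missing="report")
    if idx.size == 0:
        raise ValueError(f"gene set resolves to no genes (unresolved: {unresolved})")
    ln = ds.layers["lognorm"]
    gene_means = np.asarray(ln.mean(axis=0)).ravel()
    # rank-based equal-size bins; ties broken by gene id for determinism
    order = np.lexsort((ds.gene_ids, gene_means))
    bin_of = np.empty(ds.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, ds.n_genes))):
        bin_of[chunk] = b
    ctrl: list[int] = []
    for j in sorted(idx):  # per-gene streams keep scores gene-order invariant
        rng = np.random.default_rng([int(seed), int(j)])
        pool = np.where(bin_of == bin_of[j])[0]
        ctrl.extend(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.asarray(ctrl)
    set_mean = np.asarray(ln[:, idx].mean(axis=1)).ravel()
    ctrl_mat = ln[:, ctrl_idx]
    if sp.issparse(ctrl_mat):
        ctrl_mean = np.asarray(ctrl_mat.mean(axis=1)).ravel()
    else:
        ctrl_mean = ctrl_mat.mean(axis=1)
    return set_mean - ctrl_mean


def assign_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """Phase per cell: G1 when both scores <= 0, else the larger score's
    phase; an exact positive tie goes to G2M with a warning."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if s.shape != g.shape:
        raise ValueError("score vectors differ in length")
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s > g, "S", "G2M"))
    ties = (s == g) & (s > 0)
    if ties.any():
        warnings.warn(f"{int(ties.sum())} cells with exactly tied positive scores -> G2M", stacklevel=2)
    return phase.astype(object)


def score_cell_cycle(
    ds: ExpressionDataset,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score both phase programmes and assign a phase to every cell.

    Results are returned indexed by cell id and written into
    ``cell_meta["phase"]``.
    """
    s = score_gene_set(ds, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m = score_gene_set(ds, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    phase = assign_phase(s, g2m)
    out = pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase},
        index=pd.Index(ds.cell_ids, name="cell_id"),
    )
    ds.cell_meta["phase"] = phase
    ds.log_op("score_cell_cycle", n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return out


class PhaseCompositionResult:
    """Chi-square test of phase composition across clusters with per-cluster
    (cluster vs rest) post-hoc tests, Bonferroni-adjusted by the number of
    clusters."""

    def __init__(self, statistic: float, p_value: float, dof: int, table: pd.DataFrame, posthoc: pd.DataFrame):
        self.statistic = statistic
        self.p_value = p_value
        self.dof = dof
        self.table = table
        self.posthoc = posthoc

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhaseCompositionResult(chi2={self.statistic:.3f}, p={self.p_value:.3g}, "
            f"dof={self.dof}, clusters={len(self.posthoc)})"
        )


def chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square without continuity correction on a contingency
    table; returns (statistic, p, dof)."""
    stat, p, dof, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p), int(dof)


def phase_composition_test(phases: np.ndarray, clusters: np.ndarray) -> PhaseCompositionResult:
    """Overall clusters x phases chi-square plus cluster-vs-rest post-hocs.

    Phases absent from every cell are dropped from the table with a
    warning. Requires at least 2 clusters.
    """
    phases = np.asarray(phases, dtype=object)
    labels = np.asarray(clusters)
    table = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(phases, name="phase"))
    missing = [p for p in PHASES if p not in table.columns]
    if missing:
        warnings.warn(f"phases absent everywhere, dropped: {missing}", stacklevel=2)
    table = table[[p for p in PHASES if p in table.columns]]
    if table.shape[0] < 2:
        raise ValueError("need at least 2 clusters for a composition test")
    stat, p, dof = chi_square(table.to_numpy())

    n_clusters = table.shape[0]
    rows = []
    total = table.sum(axis=0)
    for c in table.index:
        sub = np.vstack([table.loc[c].to_numpy(), (total - table.loc[c]).to_numpy()])
        sub = sub[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2 or (sub.sum(axis=1) == 0).any():
            rows.append({"cluster": c, "chi2": np.nan, "p": np.nan, "p_adjusted": np.nan})
            continue
        cs, cp, _ = chi_square(sub)
        rows.append({"cluster": c, "chi2": cs, "p": cp, "p_adjusted": min(1.0, cp * n_clusters)})
    posthoc = pd.DataFrame(rows).set_index("cluster")
    return PhaseCompositionResult(stat, p, dof, table, posthoc)
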