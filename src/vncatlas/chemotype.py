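"""Per-cell transmitter classification and cluster-level chemotype summaries.

A cell is called positive for a transmitter class when any of that class's
marker genes is detected: acetylcholine (VAChT or ChAT), GABA (GAT or Gad1),
glutamate (VGlut), and the pan-monoamine class (Vmat). "Detected" defaults
to a nonzero count (lognorm > 0); the threshold is configurable. A strict
acetylcholine mode requires the vesicular transporter VAChT itself, since
ChAT alone can over-call cholinergic identity in co-expressing cells.

Cluster-level rules implemented here:

* predominance — a cluster is labelled with the fast-acting transmitter
  whose markers are detected in more than 70% of its cells;
* neuropeptide calling — a neuropeptide gene is assigned to a cluster when
  it is expressed in more than 25% of the cluster's cells with an average
  scaled (z-scored) expression above 1.0, both strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import (
    MONOAMINE_SUBTYPE_MARKERS,
    TRANSMITTER_MARKERS,
    ExpressionDataset,
    GeneSetCatalog,
)
from .preprocess import scale

__all__ = [
    "classify_cells",
    "combination_histogram",
    "cluster_class_fractions",
    "cluster_predominance",
    "call_neuropeptide_clusters",
    "NeuropeptideCalls",
    "subset_by_gene",
    "fraction_without_transmitter",
    "summarize_gene_set_by_cluster",
]

FAN_CLASSES = ("ACh", "GABA", "Glu")
MAIN_CLASSES = ("ACh", "GABA", "Glu", "Monoamine")


def _detected(ds: ExpressionDataset, genes: list[str], threshold: float) -> np.ndarray:
    """Per-cell boolean: any listed gene with lognorm above threshold."""
    idx, _ = ds.resolve_genes(genes)  # raises listing unresolved markers
    layer = ds.layers.get("lognorm", ds.counts)
    sub = layer[:, idx]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    return (sub > threshold).any(axis=1)


def classify_cells(
    ds: ExpressionDataset,
    catalog: GeneSetCatalog | None = None,
    detection_threshold: float = 0.0,
    strict_ach: bool = False,
) -> pd.DataFrame:
    """Per-cell transmitter flags and class count.

    Returns a frame indexed by cell id with boolean columns for the four
    main classes, the monoamine subtype annotations (octopamine, serotonin,
    dopamine), and ``n_classes`` (number of main classes detected, 0-4).
    With ``strict_ach``, the acetylcholine call requires VAChT; ChAT alone
    does not qualify.
    """
    cat = catalog or GeneSetCatalog.default()
    tmap = cat.transmitter_map
    out = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
    for cls in MAIN_CLASSES:
        markers = tmap[cls]
        if cls == "ACh" and strict_ach:
            markers = [m for m in markers if m != "ChAT"] or markers
        out[cls] = _detected(ds, markers, detection_threshold)
    for sub, markers in MONOAMINE_SUBTYPE_MARKERS.items():
        genes = cat.sets.get(sub, list(markers))
        out[sub] = _detected(ds, genes, detection_threshold)
    out["n_classes"] = out[list(MAIN_CLASSES)].sum(axis=1).astype(int)
    return out


def combination_histogram(flags: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of cells over number of classes and over each observed
    flag combination.

    Returns ``(by_n, by_combo)``; percentages are exact on the counts, so
    the ``by_n`` percentages sum to 100.
    """
    total = len(flags)
    if total == 0:
        raise ValueError("empty flag table")
    by_n = (
        flags["n_classes"].value_counts().reindex(range(5), fill_value=0).rename("count").to_frame()
    )
    by_n.index.name = "n_classes"
    by_n["pct"] = 100.0 * by_n["count"] / total

    combo = flags[list(MAIN_CLASSES)].apply(
        lambda row: "+".join([c for c in MAIN_CLASSES if row[c]]) or "none", axis=1
    )
    by_combo = combo.value_counts().rename("count").to_frame()
    by_combo.index.name = "combination"
    by_combo["pct"] = 100.0 * by_combo["count"] / total
    return by_n, by_combo


def cluster_class_fractions(
    flags: pd.DataFrame, clusters: np.ndarray, classes: tuple[str, ...] = MAIN_CLASSES
) -> pd.DataFrame:
    """Per-cluster fraction of cells positive for each class."""
    labels = np.asarray(clusters)
    if len(labels) != len(flags):
        raise ValueError("clusters length != number of cells")
    df = flags[list(classes)].copy()
    df["cluster"] = labels
    return df.groupby("cluster").mean()


def cluster_predominance(
    flags: pd.DataFrame, clusters: np.ndarray, threshold: float = 0.70
) -> pd.DataFrame:
    """Label each cluster with its predominant fast-acting transmitter.

    A cluster is labelled with the FAN class whose positive fraction
    strictly exceeds ``threshold``; if no class qualifies the label is
    "none". Because transmitter flags can co-occur within a cell, two
    classes may both exceed the threshold: the larger fraction wins, and an
    exact tie falls back to "none" with a warning. Thresholds below 0.5 are
    rejected.
    """
    if threshold < 0.5:
        raise ValueError("predominance threshold must be >= 0.5")
    frac = cluster_class_fractions(flags, clusters, classes=FAN_CLASSES)
    labels = []
    for c, row in frac.iterrows():
        above = row[row > threshold]
        if len(above) == 0:
            labels.append("none")
        elif len(above) == 1 or above.max() > above.sort_values().iloc[-2]:
            labels.append(above.idxmax())
        else:
            warnings.warn(f"cluster {c}: tied predominant fractions; labelled none", stacklevel=2)
            labels.append("none")
    out = frac.copy()
    out["predominant"] = labels
    out["threshold"] = threshold
    return out


@dataclass
class NeuropeptideCalls:
    """Per (cluster, gene) neuropeptide expression calls with summaries."""

    table: pd.DataFrame  # cluster, gene, pct_expressing, mean_scaled, called
    unresolved: list[str]

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    @property
    def peptidergic_clusters(self) -> list[int]:
        return sorted(self.called["cluster"].unique().tolist())

    @property
    def multi_cluster_genes(self) -> list[str]:
        counts = self.called.groupby("gene")["cluster"].nunique()
        return sorted(counts[counts > 1].index.tolist())


def call_neuropeptide_clusters(
    ds: ExpressionDataset,
    np_genes: list[str],
    clusters: np.ndarray | None = None,
    pct_min: float = 0.25,
    scaled_min: float = 1.0,
) -> NeuropeptideCalls:
    """Call neuropeptide genes per cluster: expressed in > ``pct_min`` of
    the cluster's cells with mean scaled expression > ``scaled_min``.

    The scaled layer is recomputed over the full gene set when absent, so
    neuropeptide genes outside the HVG set still have defined z-scores.
    Genes missing from the dataset are reported and excluded.
    """
    labels = np.asarray(ds.cell_meta["cluster"] if clusters is None else clusters)
    idx, unresolved = ds.resolve_genes(np_genes, missing="report")
    if "scaled" not in ds.layers or np.all(np.asarray(ds.layers["scaled"])[:, idx] == 0):
        scale(ds)
    scaled = np.asarray(ds.layers["scaled"])[:, idx]
    expressed = np.asarray((ds.counts[:, idx] > 0).todense())
    resolved_names = [g for g in np_genes if g not in set(unresolved)]
    rows = []
    for c in np.unique(labels):
        m = labels == c
        pct = expressed[m].mean(axis=0)
        mean_scaled = scaled[m].mean(axis=0)
        for g, p, s in zip(resolved_names, pct, mean_scaled):
            rows.append(
                {
                    "cluster": int(c),
                    "gene": g,
                    "pct_expressing": float(p),
                    "mean_scaled": float(s),
                    "called": bool((p > pct_min) and (s > scaled_min)),
                }
            )
    return NeuropeptideCalls(table=pd.DataFrame(rows), unresolved=unresolved)


def subset_by_gene(
    ds: ExpressionDataset, gene: str, min_lognorm: float = 1.0
) -> ExpressionDataset:
    """Retain cells whose normalized expression of ``gene`` strictly exceeds
    ``min_lognorm`` — the rule used to pull out dopaminergic (TH > 1) and
    serotonergic (SerT > 1) cells for sub-analysis."""
    if "lognorm" not in ds.layers:
        raise ValueError("run log_normalize first")
    vec = ds.gene_vector(gene, layer="lognorm")
    out = ds.subset_cells(vec > min_lognorm)
    out.log_op("subset_by_gene", gene=gene, min_lognorm=min_lognorm, n_cells=out.n_cells)
    return out


def fraction_without_transmitter(flags: pd.DataFrame, clusters: np.ndarray) -> pd.Series:
    """Per-cluster fraction of cells with no transmitter class detected."""
    labels = np.asarray(clusters)
    none = (flags["n_classes"] == 0).to_numpy()
    return pd.Series(none).groupby(labels).mean().rename("fraction_no_transmitter")


def summarize_gene_set_by_cluster(
    ds: ExpressionDataset, genes: list[str], clusters: np.ndarray | None = None
) -> pd.DataFrame:
    """Dot-plot style summary: per cluster x gene, the fraction of cells
    expressing (count > 0), mean lognorm, and mean scaled expression."""
    labels = np.asarray(ds.cell_meta["cluster"] if clusters is None else clusters)
    idx, unresolved = ds.resolve_genes(genes, missing="report")
    if unresolved:
        warnings.warn(f"gene-set summary: unresolved genes {unresolved}", stacklevel=2)
    resolved_names = [g for g in genes if g not in set(unresolved)]
    expressed = np.asarray((ds.counts[:, idx] > 0).todense())
    ln = ds.layers.get("lognorm")
    lognorm = np.asarray(ln[:, idx].todense()) if ln is not None else np.zeros_like(expressed, dtype=float)
    scaled_layer = ds.layers.get("scaled")
    scaled = (
        np.asarray(scaled_layer)[:, idx] if scaled_layer is not None else np.zeros_like(lognorm)
    )
    rows = []
    for c in np.unique(labels):
        m = labels == c
        for k, g in enumerate(resolved_names):
            rows.append(
                {
                    "cluster": int(c),
                    "gene": g,
                    "pct_expressing": float(expressed[m, k].mean()),
                    "mean_lognorm": float(lognorm[m, k].mean()),
                    "mean_scaled": float(scaled[m, k].mean()),
                }
            )
    return pd.DataFrame(rows)
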