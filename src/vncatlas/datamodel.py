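"""Core in-memory containers: the expression dataset and gene-set catalog.

The canonical orientation is cells x genes, regardless of the on-disk
convention of the 10x triple (which stores genes x cells). Gene identity is
two-level: a unique accession (``gene_ids``) plus a possibly non-unique
display symbol (``gene_symbols``); resolution tries accessions first and
falls back to unambiguous symbols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "GeneSetCatalog",
    "GeneResolutionError",
    "TRANSMITTER_MARKERS",
    "MONOAMINE_SUBTYPE_MARKERS",
    "FAMILY_NAMES",
]

#: Transmitter class -> marker gene symbols. A cell is called positive for a
#: class when any of its markers is detected. ACh and GABA have two markers
#: each (vesicular transporter + synthesis enzyme); Glu and the pan-monoamine
#: class are single-marker.
TRANSMITTER_MARKERS: dict[str, tuple[str, ...]] = {
    "ACh": ("VAChT", "ChAT"),
    "GABA": ("GAT", "Gad1"),
    "Glu": ("VGlut",),
    "Monoamine": ("Vmat",),
}

#: Monoamine subtypes are annotations layered on top of the four main
#: classes, not mutually exclusive categories.
MONOAMINE_SUBTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "octopamine": ("Tbh",),
    "serotonin": ("SerT",),
    "dopamine": ("TH", "Dat"),
}

#: Reserved gene-family names used by QC percentage metrics.
FAMILY_NAMES = ("mito", "ribo", "heat_shock")


class GeneResolutionError(KeyError):
    """Raised when a requested gene cannot be resolved unambiguously."""


def _as_str_array(values: Iterable[str]) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class ExpressionDataset:
    """Raw counts plus derived layers and per-cell annotations.

    counts is a sparse cells x genes matrix of non-negative integers.
    ``layers`` holds derived real-valued matrices of identical shape
    ("lognorm", "scaled", "imputed"); ``embeddings`` holds low-dimensional
    per-cell coordinates (e.g. "pca"); ``cell_meta`` is indexed by cell id
    and carries cluster labels, phases and chemotype flags; ``params`` is an
    append-only provenance log of the operations applied.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    layers: dict = field(default_factory=dict)
    cell_meta: pd.DataFrame | None = None
    embeddings: dict = field(default_factory=dict)
    params: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.gene_symbols is None:
            self.gene_symbols = self.gene_ids.copy()
        self.gene_symbols = _as_str_array(self.gene_symbols)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    # ------------------------------------------------------------------ shape
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != g or len(self.gene_symbols) != g:
            raise ValueError(f"gene id/symbol length does not match {g} matrix columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell barcodes in input")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene accessions in input")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != counts shape")
        if len(self.cell_meta) != n or not np.array_equal(
            np.asarray(self.cell_meta.index, dtype=object), self.cell_ids
        ):
            raise ValueError("cell_meta index must equal cell_ids")

    def log_op(self, op: str, **kwargs) -> None:
        self.params.append({"op": op, **kwargs})

    # ------------------------------------------------------------- resolution
    def resolve_genes(
        self, names: Sequence[str], missing: str = "error"
    ) -> tuple[np.ndarray, list[str]]:
        """Map gene names to column indices.

        Accessions are matched first; a name that is not an accession is
        matched as a symbol, and an ambiguous symbol (shared by several
        accessions) raises :class:`GeneResolutionError` listing candidates.

        Parameters
        ----------
        missing:
            "error" raises on any unresolved name, "report" returns them in
            the second element of the result.
        """
        id_index = {g: i for i, g in enumerate(self.gene_ids)}
        sym_index: dict[str, list[int]] = {}
        for i, s in enumerate(self.gene_symbols):
            sym_index.setdefault(s, []).append(i)
        idx: list[int] = []
        unresolved: list[str] = []
        for name in names:
            if name in id_index:
                idx.append(id_index[name])
            elif name in sym_index:
                hits = sym_index[name]
                if len(hits) > 1:
                    raise GeneResolutionError(
                        f"symbol {name!r} is ambiguous; candidates: "
                        f"{[self.gene_ids[i] for i in hits]}"
                    )
                idx.append(hits[0])
            else:
                unresolved.append(name)
        if unresolved and missing == "error":
            raise GeneResolutionError(f"unresolved genes: {unresolved}")
        return np.asarray(idx, dtype=int), unresolved

    def gene_vector(self, name: str, layer: str | None = None) -> np.ndarray:
        """Dense per-cell vector for one gene, from counts or a layer."""
        (j,), _ = self.resolve_genes([name])
        mat = self.counts if layer is None else self.layers[layer]
        col = mat[:, j]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()

    # -------------------------------------------------------------- subsetting
    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """Restrict to masked cells; layers, embeddings and metadata follow."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValueError(f"mask length {mask.size} != {self.n_cells} cells")
        if not mask.any():
            warnings.warn("subset_cells: mask selects no cells", stacklevel=2)
        out = ExpressionDataset(
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            layers={k: v[mask] for k, v in self.layers.items()},
            cell_meta=self.cell_meta.loc[mask].copy(),
            embeddings={k: v[mask] for k, v in self.embeddings.items()},
            params=list(self.params),
        )
        out.log_op("subset_cells", n_before=self.n_cells, n_after=int(mask.sum()))
        return out

    def subset_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_genes,):
            raise ValueError(f"mask length {mask.size} != {self.n_genes} genes")
        out = ExpressionDataset(
            counts=self.counts[:, mask],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[mask],
            gene_symbols=self.gene_symbols[mask],
            layers={k: v[:, mask] for k, v in self.layers.items()},
            cell_meta=self.cell_meta.copy(),
            embeddings=dict(self.embeddings),
            params=list(self.params),
        )
        out.log_op("subset_genes", n_before=self.n_genes, n_after=int(mask.sum()))
        return out

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            gene_symbols=self.gene_symbols.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
            cell_meta=self.cell_meta.copy(),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
            params=list(self.params),
        )

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata as ad

        var = pd.DataFrame(
            {"gene_symbol": self.gene_symbols}, index=pd.Index(self.gene_ids, name="gene_id")
        )
        adata = ad.AnnData(X=self.counts.copy(), obs=self.cell_meta.copy(), var=var)
        for k, v in self.layers.items():
            adata.layers[k] = v.copy()
        for k, v in self.embeddings.items():
            adata.obsm[f"X_{k}"] = v.copy()
        return adata


@dataclass
class GeneSetCatalog:
    """Named gene sets: transmitter markers, QC families, phase lists, etc.

    ``sets`` maps a set name to gene identifiers (accessions or symbols);
    reserved names ``mito``/``ribo``/``heat_shock`` act as the QC families
    and the transmitter classes of :data:`TRANSMITTER_MARKERS` act as the
    per-cell classification map unless overridden.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len({k for k in self.sets}):
            raise ValueError("duplicate set names")

    @classmethod
    def default(cls) -> "GeneSetCatalog":
        """Catalog of the built-in transmitter and monoamine marker symbols."""
        sets = {k: list(v) for k, v in TRANSMITTER_MARKERS.items()}
        sets.update({k: list(v) for k, v in MONOAMINE_SUBTYPE_MARKERS.items()})
        return cls(sets=sets)

    @property
    def families(self) -> dict[str, list[str]]:
        return {f: self.sets.get(f, []) for f in FAMILY_NAMES}

    @property
    def transmitter_map(self) -> dict[str, list[str]]:
        out = {}
        for cls_name, default in TRANSMITTER_MARKERS.items():
            out[cls_name] = list(self.sets.get(cls_name, default))
        return out

    def get(self, name: str) -> list[str]:
        if name not in self.sets:
            raise KeyError(f"no gene set named {name!r}; have {sorted(self.sets)}")
        return list(self.sets[name])

    def update(self, other: Mapping[str, Sequence[str]]) -> None:
        for k, v in other.items():
            self.sets[k] = list(v)

    def resolution_report(self, ds: ExpressionDataset) -> pd.DataFrame:
        """Per set: how many genes resolve against ``ds`` and which do not.

        Unresolvable entries are reported, never silently dropped.
        """
        rows = []
        for name, genes in self.sets.items():
            _, unresolved = ds.resolve_genes(genes, missing="report")
            rows.append(
                {
                    "set_name": name,
                    "n_genes": len(genes),
                    "n_resolved": len(genes) - len(unresolved),
                    "unresolved": ";".join(unresolved),
                }
            )
        return pd.DataFrame(rows).set_index("set_name")
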