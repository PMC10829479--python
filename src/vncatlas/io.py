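"""Readers and writers for the 10x MTX triple, dense TSV matrices, gene-set
catalogs and ROI measurement tables."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import ExpressionDataset, GeneSetCatalog

__all__ = [
    "read_mtx_triple",
    "write_mtx_triple",
    "read_dense_tsv",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_roi_csv",
    "FormatError",
]


class FormatError(ValueError):
    """A file is missing or does not follow the expected on-disk convention."""


_MATRIX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")


def _find(directory: Path, candidates: tuple[str, ...], what: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"no {what} file in {directory} (looked for {', '.join(candidates)})")


def _read_tsv_noheader(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_mtx_triple(directory: str | Path) -> ExpressionDataset:
    """Read a CellRanger-style sparse triple into a cells x genes dataset.

    On disk the matrix is genes x cells; it is transposed at read time.
    Features contribute accessions (column 1) and symbols (column 2, falling
    back to the accession when absent).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx_path = _find(directory, _MATRIX_NAMES, "matrix")
    feat_path = _find(directory, _FEATURE_NAMES, "features")
    bc_path = _find(directory, _BARCODE_NAMES, "barcodes")

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)).T)
    features = _read_tsv_noheader(feat_path)
    barcodes = _read_tsv_noheader(bc_path)

    if len(features) != mat.shape[1]:
        raise FormatError(
            f"feature table has {len(features)} rows but matrix has {mat.shape[1]} genes"
        )
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"barcode table has {len(barcodes)} rows but matrix has {mat.shape[0]} cells"
        )
    gene_ids = features[0].to_numpy(dtype=object)
    gene_symbols = (
        features[1].to_numpy(dtype=object) if features.shape[1] > 1 else gene_ids.copy()
    )
    ds = ExpressionDataset(
        counts=mat,
        cell_ids=barcodes[0].to_numpy(dtype=object),
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
    )
    ds.log_op("read_mtx_triple", directory=str(directory))
    return ds


def write_mtx_triple(ds: ExpressionDataset, directory: str | Path) -> Path:
    """Write the 10x triple (genes x cells on disk); integer-exact round trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(ds.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    feat = pd.DataFrame(
        {0: ds.gene_ids, 1: ds.gene_symbols, 2: ["Gene Expression"] * ds.n_genes}
    )
    feat.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    return directory


def read_dense_tsv(path: str | Path, orientation: str = "cells") -> ExpressionDataset:
    """Read a dense TSV count matrix.

    With ``orientation="cells"`` rows are cells (index = barcode, columns =
    gene ids); ``"genes"`` reads the transpose.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes":
        df = df.T
    elif orientation != "cells":
        raise ValueError("orientation must be 'cells' or 'genes'")
    counts = sp.csr_matrix(df.to_numpy())
    ds = ExpressionDataset(
        counts=counts,
        cell_ids=df.index.astype(str).to_numpy(dtype=object),
        gene_ids=df.columns.astype(str).to_numpy(dtype=object),
        gene_symbols=None,
    )
    ds.log_op("read_dense_tsv", path=str(path), orientation=orientation)
    return ds


def read_gene_catalog(path: str | Path) -> GeneSetCatalog:
    """Read a catalog TSV with columns ``set_name`` and ``gene_id``.

    A third column ``gene_symbol`` is accepted and used as the identifier
    when ``gene_id`` is empty.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (FileNotFoundError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read catalog {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"catalog {path} has no rows")
    required = {"set_name", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"catalog {path} must have columns {sorted(required)}")
    sets: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        gene = row["gene_id"]
        if (pd.isna(gene) or gene == "") and "gene_symbol" in df.columns:
            gene = row["gene_symbol"]
        if pd.isna(gene) or gene == "":
            raise FormatError(f"catalog {path}: empty gene entry in set {row['set_name']!r}")
        sets.setdefault(str(row["set_name"]), []).append(str(gene))
    return GeneSetCatalog(sets=sets)


def write_gene_catalog(catalog: GeneSetCatalog, path: str | Path) -> Path:
    rows = [
        {"set_name": name, "gene_id": gene}
        for name, genes in catalog.sets.items()
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)
    return Path(path)


#: ImageJ "Measure" column names accepted as aliases in ROI tables.
_ROI_ALIASES = {
    "IntDen": "integrated_density",
    "RawIntDen": "integrated_density",
    "Area": "area",
    "Mean": "background_mean",
    "X": "x",
    "Y": "y",
}


def read_roi_csv(path: str | Path) -> pd.DataFrame:
    """Read an ROI measurement table, normalising ImageJ column names."""
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in _ROI_ALIASES.items() if k in df.columns})
    missing = {"integrated_density", "area", "background_mean"} - set(df.columns)
    if missing:
        raise FormatError(f"ROI table {path} lacks columns {sorted(missing)}")
    if (df["area"] <= 0).any():
        raise FormatError(f"ROI table {path} has non-positive areas")
    return df
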