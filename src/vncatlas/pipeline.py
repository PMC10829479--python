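"""Stage orchestration: simulate -> qc -> cluster -> chemotype / cellcycle /
markers / impute-correlate / cytometry -> report.

Stages hand artifacts to each other through files under one output
directory, so any stage can be rerun independently; a missing prerequisite
raises an error naming the stage that produces it. One global seed fans out
to per-stage seeds through a stage-name hash, making every stage
independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellcycle as cc
from . import chemotype as ct
from . import cytometry as cy
from . import imputation as imp
from . import markers as mk
from .clustering import ClusteringConfig, embed_and_cluster
from .datamodel import ExpressionDataset, GeneSetCatalog
from .io import read_gene_catalog, read_mtx_triple, read_roi_csv
from .preprocess import log_normalize, scale, select_hvg
from .qc import QCThresholds, apply_qc
from .simulate import SimConfig, generate, generate_roi_table, write_bundle

__all__ = ["Pipeline", "stage_seed", "load_config", "DEFAULT_CONFIG", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32(stage) xor global, mod 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "qc": {},
    "cluster": {"n_hvg": 2000, "n_pcs": 35, "resolution": 0.8, "n_neighbors": 20},
    "chemotype": {"detection_threshold": 0.0, "strict_ach": False, "predominance_threshold": 0.70},
    "cellcycle": {"n_bins": 24, "n_ctrl": 100},
    "markers": {"min_pct": 0.5, "lfc_threshold": 0.32},
    "impute": {"k": 5, "alpha": 1.0, "t": 3, "n_pcs": 20, "target_gene": "SerT"},
    "cytometry": {"n_rois": 120, "roi_csv": None},
}

_SIM_KEYS = {
    "n_cells", "n_genes", "mean_umi", "libsize_sigma", "dispersion", "marker_baseline",
    "mito_share", "ribo_share", "hs_share", "qc_fail_fractions", "doublet_rate",
    "phase_fractions", "phase_mult", "np_pct",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config over the defaults, rejecting unknown keys."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    for source in (user, overrides or {}):
        for key, value in source.items():
            if key not in cfg:
                raise PipelineError(f"unknown config block {key!r}; known: {sorted(cfg)}")
            if isinstance(cfg[key], dict):
                for sub, sval in value.items():
                    if key == "simulate":
                        if sub not in _SIM_KEYS and sub != "qc_thresholds":
                            raise PipelineError(f"unknown simulate key {sub!r}")
                    elif sub not in cfg[key] and key != "qc":
                        raise PipelineError(f"unknown key {key}.{sub}")
                    cfg[key][sub] = sval
            else:
                cfg[key] = value
    return cfg


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


class Pipeline:
    """Run the stages against one output directory."""

    def __init__(self, config: dict | None = None, outdir: str | Path = "vncatlas_out"):
        self.config = config or load_config()
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config.get("seed", 0))

    # ------------------------------------------------------------- helpers
    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise PipelineError(f"missing {path.name}; run the {producer!r} stage first")
        return path

    def _sim_config(self) -> SimConfig:
        block = dict(self.config.get("simulate", {}))
        thr = block.pop("qc_thresholds", None)
        kwargs = {k: v for k, v in block.items() if k in _SIM_KEYS}
        if "phase_fractions" in kwargs:
            kwargs["phase_fractions"] = dict(kwargs["phase_fractions"])
        if "qc_fail_fractions" in kwargs:
            kwargs["qc_fail_fractions"] = dict(kwargs["qc_fail_fractions"])
        if thr is not None:
            kwargs["qc_thresholds"] = QCThresholds(**thr)
        return SimConfig(seed=stage_seed(self.seed, "simulate"), **kwargs)

    def _load_raw(self) -> tuple[ExpressionDataset, GeneSetCatalog]:
        mdir = self._require(self.outdir / "matrix", "simulate")
        cat = read_gene_catalog(self._require(self.outdir / "catalog.tsv", "simulate"))
        return read_mtx_triple(mdir), cat

    def _load_qc(self) -> tuple[ExpressionDataset, GeneSetCatalog]:
        mdir = self._require(self.outdir / "qc_matrix", "qc")
        cat = read_gene_catalog(self._require(self.outdir / "catalog.tsv", "simulate"))
        return read_mtx_triple(mdir), cat

    def _load_clusters(self, ds: ExpressionDataset) -> np.ndarray:
        path = self._require(self.outdir / "clusters.csv", "cluster")
        table = pd.read_csv(path).set_index("cell_id")["cluster"]
        labels = table.reindex(ds.cell_ids)
        if labels.isna().any():
            raise PipelineError("clusters.csv does not cover the QC'd cells; rerun 'cluster'")
        ds.cell_meta["cluster"] = labels.to_numpy(dtype=int)
        return ds.cell_meta["cluster"].to_numpy()

    def _prepped(self) -> tuple[ExpressionDataset, GeneSetCatalog]:
        ds, cat = self._load_qc()
        log_normalize(ds)
        hvg = select_hvg(ds, n=int(self.config["cluster"].get("n_hvg", 2000)))
        scale(ds)
        ds._hvg = hvg  # cached for embed stage
        return ds, cat

    # -------------------------------------------------------------- stages
    def simulate(self) -> dict:
        cfg = self._sim_config()
        ds, truth = generate(cfg)
        write_bundle(ds, truth, self.outdir)
        return {"n_cells": ds.n_cells, "n_genes": ds.n_genes}

    def qc(self) -> dict:
        ds, cat = self._load_raw()
        thr_cfg = dict(self.config.get("qc", {}))
        if thr_cfg:
            thresholds = QCThresholds(**thr_cfg)
        else:
            thresholds = self._sim_config().qc_thresholds
        filtered, report = apply_qc(ds, cat, thresholds)
        report.to_csv(self.outdir / "qc_report.csv")
        from .io import write_mtx_triple

        write_mtx_triple(filtered, self.outdir / "qc_matrix")
        return {
            "cells_before": ds.n_cells,
            "cells_after": filtered.n_cells,
            "genes_before": ds.n_genes,
            "genes_after": filtered.n_genes,
        }

    def cluster(self) -> dict:
        ds, _ = self._prepped()
        blk = self.config["cluster"]
        cfg = ClusteringConfig(
            n_hvg=int(blk.get("n_hvg", 2000)),
            n_pcs=int(blk.get("n_pcs", 35)),
            resolution=float(blk.get("resolution", 0.8)),
            n_neighbors=int(blk.get("n_neighbors", 20)),
            seed=stage_seed(self.seed, "cluster"),
        )
        labels = embed_and_cluster(ds, genes=ds._hvg, config=cfg)
        pd.DataFrame({"cell_id": ds.cell_ids, "cluster": labels}).to_csv(
            self.outdir / "clusters.csv", index=False
        )
        return {"n_clusters": int(labels.max() + 1)}

    def chemotype(self) -> dict:
        ds, cat = self._prepped()
        clusters = self._load_clusters(ds)
        blk = self.config["chemotype"]
        flags = ct.classify_cells(
            ds, cat,
            detection_threshold=float(blk.get("detection_threshold", 0.0)),
            strict_ach=bool(blk.get("strict_ach", False)),
        )
        flags.to_csv(self.outdir / "chemotype.csv")
        by_n, by_combo = ct.combination_histogram(flags)
        by_n.to_csv(self.outdir / "combination_histogram.csv")
        by_combo.to_csv(self.outdir / "combinations.csv")
        pred = ct.cluster_predominance(
            flags, clusters, threshold=float(blk.get("predominance_threshold", 0.70))
        )
        pred.to_csv(self.outdir / "predominance.csv")
        calls = ct.call_neuropeptide_clusters(ds, cat.get("neuropeptide"), clusters)
        calls.table.to_csv(self.outdir / "np_calls.csv", index=False)
        return {
            "class_fractions": {c: float(flags[c].mean()) for c in ct.MAIN_CLASSES},
            "combination_pct": {str(k): float(v) for k, v in by_n["pct"].items()},
            "predominance": {str(k): str(v) for k, v in pred["predominant"].items()},
            "np_called": [
                {"cluster": int(r.cluster), "gene": r.gene} for r in calls.called.itertuples()
            ],
        }

    def cellcycle(self) -> dict:
        ds, cat = self._prepped()
        clusters = self._load_clusters(ds)
        blk = self.config["cellcycle"]
        scores = cc.score_cell_cycle(
            ds,
            cat.get("s_phase"),
            cat.get("g2m_phase"),
            n_bins=int(blk.get("n_bins", 24)),
            n_ctrl=int(blk.get("n_ctrl", 100)),
            seed=stage_seed(self.seed, "cellcycle"),
        )
        scores.to_csv(self.outdir / "phases.csv")
        result = cc.phase_composition_test(scores["phase"].to_numpy(), clusters)
        result.posthoc.to_csv(self.outdir / "phase_test.csv")
        return {
            "phase_counts": {str(k): int(v) for k, v in scores["phase"].value_counts().items()},
            "chi2": float(result.statistic),
            "chi2_p": float(result.p_value),
        }

    def markers(self) -> dict:
        ds, _ = self._prepped()
        self._load_clusters(ds)
        blk = self.config["markers"]
        table = mk.find_all_markers(
            ds,
            min_pct=float(blk.get("min_pct", 0.5)),
            lfc_threshold=float(blk.get("lfc_threshold", 0.32)),
        )
        table.to_csv(self.outdir / "markers.csv", index=False)
        return {
            "n_marker_rows": int(len(table)),
            "n_significant": int((table["p_adjusted"] < 0.05).sum()),
        }

    def correlate(self) -> dict:
        ds, _ = self._prepped()
        blk = self.config["impute"]
        from sklearn.decomposition import PCA

        X = np.asarray(ds.layers["scaled"])
        n_pcs = min(int(blk.get("n_pcs", 20)), min(X.shape) - 1)
        emb = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
        op = imp.build_diffusion_operator(emb, k=int(blk.get("k", 5)), alpha=float(blk.get("alpha", 1.0)))
        imp.impute(ds, op, t=int(blk.get("t", 3)))
        table = imp.correlate_with_gene(ds, blk.get("target_gene", "SerT"), layer="imputed")
        table.to_csv(self.outdir / "correlation.csv", index=False)
        return {
            "target_gene": blk.get("target_gene", "SerT"),
            "top_correlate": str(table.iloc[1]["gene"]),
            "top_abs_cor": float(table.iloc[1]["abs_cor"]),
        }

    impute = correlate  # one stage computes both artifacts

    def cytometry(self) -> dict:
        blk = self.config["cytometry"]
        if blk.get("roi_csv"):
            rois = read_roi_csv(blk["roi_csv"])
        else:
            rois, _ = generate_roi_table(
                n=int(blk.get("n_rois", 120)), seed=stage_seed(self.seed, "cytometry")
            )
        table = cy.ctcf_table(rois)
        table.to_csv(self.outdir / "cytometry.csv", index=False)
        frame = cy.GanglionFrame(0.0, 100.0)
        return {
            "th_class_counts": {str(k): int(v) for k, v in table["th_class"].value_counts().items()},
            "posterior_fraction": float(cy.posterior_fraction(table, frame)),
        }

    def report(self, stage_results: dict | None = None) -> dict:
        """Collate the headline numbers into report.json."""
        results = stage_results or {}
        payload = _round_floats(results)
        text = json.dumps(payload, sort_keys=True, indent=1)
        (self.outdir / "report.json").write_text(text + "\n")
        resolved = dict(self.config)
        (self.outdir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
        return payload

    def run_all(self) -> dict:
        results = {"seed": self.seed}
        results["simulate"] = self.simulate()
        results["qc"] = self.qc()
        results["cluster"] = self.cluster()
        results["chemotype"] = self.chemotype()
        results["cellcycle"] = self.cellcycle()
        results["markers"] = self.markers()
        results["correlate"] = self.correlate()
        results["cytometry"] = self.cytometry()
        return self.report(results)
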