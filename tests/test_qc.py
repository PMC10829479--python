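import math

import numpy as np
import pytest

from vncatlas.datamodel import GeneSetCatalog
from vncatlas.qc import QCThresholds, apply_qc, compute_qc_metrics, filter_cells, filter_genes
from vncatlas.simulate import SimConfig, generate

from conftest import make_dataset


def brute_force_cell_filter(counts, mito, ribo, hs, t: QCThresholds):
    """Naive per-cell loop re-implementation of the cell filter rules."""
    keep = []
    for i in range(counts.shape[0]):
        row = counts[i]
        n_umi = row.sum()
        n_gene = (row > 0).sum()
        tot = max(n_umi, 1)
        pct_m = 100 * row[mito].sum() / tot if n_umi else 0.0
        pct_r = 100 * row[ribo].sum() / tot if n_umi else 0.0
        pct_h = 100 * row[hs].sum() / tot if n_umi else 0.0
        ratio_ok = n_umi > 1 and math.log(max(n_gene, 1)) / math.log(n_umi) >= t.min_log_ratio
        keep.append(
            n_gene >= t.min_genes and n_umi >= t.min_umi and ratio_ok
            and pct_m <= t.max_pct_mito and t.min_pct_ribo <= pct_r <= t.max_pct_ribo
            and pct_h <= t.max_pct_hs
        )
    return np.asarray(keep)


def brute_force_gene_filter(counts, t: QCThresholds):
    keep = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        keep.append(col.sum() >= t.gene_min_total and (col > 0).sum() >= t.gene_min_cells)
    return np.asarray(keep)


def _random_catalog(n_genes, rng):
    fam_idx = rng.permutation(n_genes)
    mito, ribo, hs = fam_idx[:3], fam_idx[3:8], fam_idx[8:10]
    return (
        GeneSetCatalog(
            sets={
                "mito": [f"g{j}" for j in mito],
                "ribo": [f"g{j}" for j in ribo],
                "heat_shock": [f"g{j}" for j in hs],
            }
        ),
        mito,
        ribo,
        hs,
    )


class TestMetrics:
    def test_all_counts_in_mito(self):
        ds = make_dataset([[4, 3, 3, 0]])
        cat = GeneSetCatalog(sets={"mito": ["g0", "g1", "g2"], "ribo": [], "heat_shock": []})
        with pytest.warns(UserWarning):
            m = compute_qc_metrics(ds, cat)
        assert m["pct_mito"].iloc[0] == 100.0

    def test_log_ratio_arithmetic(self):
        counts = np.zeros((1, 600), dtype=int)
        counts[0, :500] = 2  # 500 genes, 1000 UMIs
        ds = make_dataset(counts)
        cat = GeneSetCatalog(sets={"mito": [], "ribo": [], "heat_shock": []})
        with pytest.warns(UserWarning):
            m = compute_qc_metrics(ds, cat)
        assert m["log_ratio"].iloc[0] == pytest.approx(math.log(500) / math.log(1000), abs=1e-12)

    def test_empty_family_warns_pct_zero(self, tiny_ds):
        cat = GeneSetCatalog(sets={"mito": [], "ribo": [], "heat_shock": []})
        with pytest.warns(UserWarning, match="resolved no genes"):
            m = compute_qc_metrics(tiny_ds, cat)
        assert (m[["pct_mito", "pct_ribo", "pct_hs"]] == 0).all().all()

    def test_log_ratio_base_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, (30, 40))
        ds = make_dataset(counts)
        cat = GeneSetCatalog(sets={"mito": [], "ribo": [], "heat_shock": []})
        m = compute_qc_metrics(ds, cat)
        ok = m["n_umi"] > 1
        alt = np.log10(m["n_gene"][ok]) / np.log10(m["n_umi"][ok])
        assert np.allclose(m["log_ratio"][ok], alt)


class TestCellFilter:
    def _metrics_row(self, **kw):
        import pandas as pd

        base = dict(n_umi=2000, n_gene=600, log_ratio=0.9, pct_mito=5.0, pct_ribo=20.0, pct_hs=1.0)
        base.update(kw)
        return pd.DataFrame([base], index=["c0"])

    def test_boundary_cell_kept(self):
        m = self._metrics_row(
            n_gene=500, n_umi=1000, log_ratio=0.8, pct_mito=18.0, pct_ribo=5.0, pct_hs=5.0
        )
        assert filter_cells(m).keep.all()

    @pytest.mark.parametrize(
        "field,value,rule",
        [
            ("n_gene", 499, "min_genes"),
            ("n_umi", 999, "min_umi"),
            ("log_ratio", 0.79, "min_log_ratio"),
            ("pct_mito", 18.01, "max_pct_mito"),
            ("pct_ribo", 4.99, "min_pct_ribo"),
            ("pct_ribo", 40.01, "max_pct_ribo"),
            ("pct_hs", 5.01, "max_pct_hs"),
        ],
    )
    def test_single_violation_attributed(self, field, value, rule):
        res = filter_cells(self._metrics_row(**{field: value}))
        assert not res.keep[0]
        assert res.violations[rule].iloc[0]
        assert res.rule_counts.drop(rule).sum() == 0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QCThresholds(min_pct_ribo=50, max_pct_ribo=40)

    def test_idempotent_on_survivors(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, (60, 50))
        ds = make_dataset(counts)
        cat, *_ = _random_catalog(50, rng)
        t = QCThresholds(min_genes=10, min_umi=50, min_log_ratio=0.3)
        m = compute_qc_metrics(ds, cat)
        keep = filter_cells(m, t).keep
        sub = ds.subset_cells(keep)
        m2 = compute_qc_metrics(sub, cat)
        assert filter_cells(m2, t).keep.all()


class TestGeneFilter:
    def test_boundary_gene_kept(self):
        # total exactly 5 in exactly 2 cells
        ds = make_dataset([[3, 10], [2, 0], [0, 0]])
        assert filter_genes(ds).tolist() == [True, False]

    def test_single_cell_gene_removed(self):
        ds = make_dataset([[10], [0], [0]])
        assert not filter_genes(ds)[0]


class TestOracleEquivalence:
    def test_masks_match_brute_force_on_random_matrices(self):
        """Vectorized filters equal the naive double-loop on random data."""
        rng = np.random.default_rng(202)
        t = QCThresholds(min_genes=5, min_umi=20, min_log_ratio=0.5)
        for _ in range(40):
            n, g = rng.integers(5, 40), rng.integers(10, 50)
            counts = rng.integers(0, 8, (n, g)) * (rng.random((n, g)) < 0.5)
            ds = make_dataset(counts)
            cat, mito, ribo, hs = _random_catalog(g, rng)
            m = compute_qc_metrics(ds, cat)
            assert np.array_equal(filter_cells(m, t).keep, brute_force_cell_filter(counts, mito, ribo, hs, t))
            assert np.array_equal(filter_genes(ds, t), brute_force_gene_filter(counts, t))


class TestApplyQC:
    def test_planted_failures_all_removed(self):
        cfg = SimConfig(
            n_cells=600,
            seed=5,
            qc_fail_fractions={"low_gene": 0.04, "high_mito": 0.03, "ribo_out": 0.02, "high_hs": 0.01},
        )
        ds, truth = generate(cfg)
        filtered, report = apply_qc(ds, truth.catalog, cfg.qc_thresholds)
        planted = truth.qc_fail_mode != ""
        kept_ids = set(filtered.cell_ids)
        assert all(cid not in kept_ids for cid in ds.cell_ids[planted])
        # survivors equal the clean cells up to binomial slack on clean losses
        clean_lost = sum(cid not in kept_ids for cid in ds.cell_ids[~planted])
        assert clean_lost <= 3 * np.sqrt(0.01 * (~planted).sum())

    def test_doublet_hook_applied_after_filters(self):
        cfg = SimConfig(n_cells=100, seed=1, doublet_rate=0.1)
        ds, truth = generate(cfg)
        doublet_ids = set(ds.cell_ids[truth.doublet])
        hook = lambda d: np.array([cid not in doublet_ids for cid in d.cell_ids])
        filtered, _ = apply_qc(ds, truth.catalog, cfg.qc_thresholds, doublet_hook=hook)
        assert not doublet_ids & set(filtered.cell_ids)
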