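from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from vncatlas.chemotype import (
    FAN_CLASSES,
    MAIN_CLASSES,
    call_neuropeptide_clusters,
    classify_cells,
    cluster_predominance,
    combination_histogram,
    fraction_without_transmitter,
    subset_by_gene,
    summarize_gene_set_by_cluster,
)
from vncatlas.datamodel import GeneResolutionError, GeneSetCatalog
from vncatlas.preprocess import log_normalize, scale
from vncatlas.simulate import CellType, SimConfig, generate

from conftest import make_dataset


def _marker_ds(rows):
    """cells x 10 transmitter-marker matrix in the canonical symbol order."""
    syms = ["VAChT", "ChAT", "GAT", "Gad1", "VGlut", "Vmat", "Tbh", "SerT", "TH", "Dat"]
    return make_dataset(rows, gene_symbols=syms)


class TestClassifyCells:
    def test_single_marker_calls(self):
        ds = _marker_ds([[3, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # VAChT only
                         [0, 0, 0, 2, 0, 0, 0, 0, 0, 0],  # Gad1 only
                         [0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])  # nothing
        f = classify_cells(ds)
        assert f.loc["c0", ["ACh", "GABA", "Glu", "Monoamine"]].tolist() == [True, False, False, False]
        assert f.loc["c0", "n_classes"] == 1
        assert f.loc["c1", "GABA"] and f.loc["c1", "n_classes"] == 1
        assert f.loc["c2", "n_classes"] == 0

    def test_strict_ach_requires_vacht(self):
        ds = _marker_ds([[0, 5, 0, 0, 0, 0, 0, 0, 0, 0]])  # ChAT only
        assert classify_cells(ds).loc["c0", "ACh"]
        assert not classify_cells(ds, strict_ach=True).loc["c0", "ACh"]

    def test_strict_never_exceeds_default(self, sim_lognorm):
        ds, _ = sim_lognorm
        default = classify_cells(ds)["ACh"].mean()
        strict = classify_cells(ds, strict_ach=True)["ACh"].mean()
        assert strict <= default

    def test_threshold_monotonicity(self, sim_lognorm):
        """Raising the detection threshold never raises any class fraction."""
        ds, _ = sim_lognorm
        prev = classify_cells(ds, detection_threshold=0.0)[list(MAIN_CLASSES)].mean()
        for thr in (0.5, 1.0, 2.0):
            cur = classify_cells(ds, detection_threshold=thr)[list(MAIN_CLASSES)].mean()
            assert (cur <= prev + 1e-12).all()
            prev = cur

    def test_unresolved_marker_errors(self, tiny_ds):
        with pytest.raises(GeneResolutionError, match="ChAT"):
            classify_cells(tiny_ds)  # tiny_ds lacks ChAT etc.

    def test_monoamine_subtypes_annotated(self):
        ds = _marker_ds([[0, 0, 0, 0, 0, 4, 0, 0, 2, 1]])  # Vmat + TH + Dat
        f = classify_cells(ds)
        assert f.loc["c0", "Monoamine"] and f.loc["c0", "dopamine"]
        assert not f.loc["c0", "serotonin"]


class TestCombinationHistogram:
    def test_hand_count(self):
        rows = [[1, 0, 0, 0, 1, 0, 0, 0, 0, 0]] * 2 + [[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]] * 8
        f = classify_cells(_marker_ds(rows))
        by_n, by_combo = combination_histogram(f)
        assert by_n.loc[2, "pct"] == 20.0
        assert by_combo.loc["ACh+Glu", "count"] == 2

    def test_percentages_sum_exact(self, sim_lognorm):
        ds, _ = sim_lognorm
        by_n, _ = combination_histogram(classify_cells(ds))
        total = sum(Fraction(int(c) * 100, int(by_n["count"].sum())) for c in by_n["count"])
        assert total == 100

    def test_all_single_class(self):
        f = classify_cells(_marker_ds([[2, 0, 0, 0, 0, 0, 0, 0, 0, 0]] * 5))
        by_n, _ = combination_histogram(f)
        assert by_n.loc[1, "pct"] == 100.0


class TestPredominance:
    def _brute(self, flags, clusters, threshold):
        out = {}
        for c in np.unique(clusters):
            sub = flags[clusters == c]
            above = {cls: sub[cls].mean() for cls in FAN_CLASSES if sub[cls].mean() > threshold}
            if not above:
                out[c] = "none"
            else:
                best = max(above.values())
                winners = [k for k, v in above.items() if v == best]
                out[c] = winners[0] if len(winners) == 1 else "none"
        return out

    def test_71_percent_rule(self):
        rows = [[0, 0, 3, 0, 0, 0, 0, 0, 0, 0]] * 71 + [[0] * 10] * 29
        f = classify_cells(_marker_ds(rows))
        pred = cluster_predominance(f, np.zeros(100, dtype=int))
        assert pred.loc[0, "predominant"] == "GABA"

    def test_50_50_none(self):
        rows = [[2, 0, 0, 0, 0, 0, 0, 0, 0, 0]] * 5 + [[0, 0, 0, 0, 3, 0, 0, 0, 0, 0]] * 5
        f = classify_cells(_marker_ds(rows))
        assert cluster_predominance(f, np.zeros(10, dtype=int)).loc[0, "predominant"] == "none"

    def test_low_threshold_rejected(self):
        f = classify_cells(_marker_ds([[1] + [0] * 9]))
        with pytest.raises(ValueError, match="0.5"):
            cluster_predominance(f, np.zeros(1, dtype=int), threshold=0.4)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = 200
            flags = pd.DataFrame({c: rng.random(n) < rng.random() for c in FAN_CLASSES})
            flags["Monoamine"] = False
            flags["n_classes"] = flags[list(FAN_CLASSES)].sum(axis=1)
            clusters = rng.integers(0, 8, n)
            got = cluster_predominance(flags, clusters)["predominant"].to_dict()
            assert got == self._brute(flags, clusters, 0.70)


class TestNeuropeptideCalls:
    def _ds_with_np(self, pct, level):
        """A 20-cell peptidergic cluster expressing NP01 in ``pct`` of its
        cells against a 100-cell background cluster (neuropeptide clusters
        are small relative to the atlas, which keeps z-scores sharp)."""
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 6, (120, 10))
        counts[:, 0] = 0
        k = int(round(pct * 20))
        counts[:k, 0] = level
        ds = make_dataset(counts, gene_symbols=["NP01"] + [f"x{i}" for i in range(9)])
        log_normalize(ds)
        scale(ds)
        ds.cell_meta["cluster"] = [0] * 20 + [1] * 100
        return ds

    def test_boundary_pct_not_called(self):
        # exactly 25% expressing -> strict inequality fails
        ds = self._ds_with_np(0.25, 50)
        calls = call_neuropeptide_clusters(ds, ["NP01"])
        row = calls.table.query("cluster == 0 and gene == 'NP01'").iloc[0]
        assert row["pct_expressing"] == 0.25 and not row["called"]

    def test_expressed_cluster_called_uniquely(self):
        ds = self._ds_with_np(0.80, 50)
        calls = call_neuropeptide_clusters(ds, ["NP01"])
        assert calls.peptidergic_clusters == [0]
        row = calls.table.query("cluster == 0 and gene == 'NP01'").iloc[0]
        assert row["called"] and row["mean_scaled"] > 1.0

    def test_unresolved_gene_reported_excluded(self):
        ds = self._ds_with_np(0.5, 50)
        calls = call_neuropeptide_clusters(ds, ["NP01", "NP99"])
        assert calls.unresolved == ["NP99"]
        assert set(calls.table["gene"]) == {"NP01"}

    def test_boundary_mean_scaled_not_called(self):
        ds = self._ds_with_np(0.8, 50)
        calls = call_neuropeptide_clusters(ds, ["NP01"], scaled_min=10.0)
        assert not calls.table["called"].any()


class TestSubsetByGene:
    def test_strict_inequality_hand_count(self):
        import scipy.sparse as sp

        ds = make_dataset([[1]] * 5, gene_symbols=["TH"])
        log_normalize(ds)
        ds.layers["lognorm"] = sp.csr_matrix(np.array([[0.0], [0.5], [1.0], [1.1], [3.0]]))
        out = subset_by_gene(ds, "TH", min_lognorm=1.0)
        assert out.n_cells == 2

    def test_threshold_zero_keeps_expressing_cells(self, sim_lognorm):
        ds, _ = sim_lognorm
        out = subset_by_gene(ds, "VGlut", min_lognorm=0.0)
        assert out.n_cells == int((ds.gene_vector("VGlut") > 0).sum())


class TestClusterSummaries:
    def test_fraction_without_transmitter_hand_count(self):
        rows = [[2, 0, 0, 0, 0, 0, 0, 0, 0, 0]] * 7 + [[0] * 10] * 3
        f = classify_cells(_marker_ds(rows))
        frac = fraction_without_transmitter(f, np.zeros(10, dtype=int))
        assert frac[0] == pytest.approx(0.3)
        by_n, _ = combination_histogram(f)
        assert frac[0] * 100 == pytest.approx(by_n.loc[0, "pct"])

    def test_dotplot_summary_hand_case(self):
        import scipy.sparse as sp

        ds = make_dataset([[0, 5], [0, 5], [1, 5], [3, 5]], gene_symbols=["HoxA", "x"])
        log_normalize(ds)
        ds.layers["lognorm"] = sp.csr_matrix(np.array([[0.0, 1], [0.0, 1], [1.0, 1], [3.0, 1]]))
        ds.cell_meta["cluster"] = [0, 0, 0, 0]
        summ = summarize_gene_set_by_cluster(ds, ["HoxA"])
        assert summ.iloc[0]["pct_expressing"] == 0.5
        assert summ.iloc[0]["mean_lognorm"] == 1.0

    def test_restricted_gene_nonzero_only_in_host_cluster(self, sim_lognorm):
        ds, truth = sim_lognorm
        ds = ds.copy()
        clusters = (truth.cell_type == "Mono").astype(int)
        ds.cell_meta["cluster"] = clusters
        summ = summarize_gene_set_by_cluster(ds, ["NP01"])
        host = summ.query("cluster == 1").iloc[0]["pct_expressing"]
        bg = summ.query("cluster == 0").iloc[0]["pct_expressing"]
        assert host > 0.5 and bg < 0.05


class TestRecovery:
    def test_planted_fraction_recovery(self):
        """Recovered class fractions match generator truth within 3 binomial SE."""
        types = (
            CellType("ACh", 0.45, ("VAChT", "ChAT")),
            CellType("GABA", 0.35, ("GAT", "Gad1")),
            CellType("Glu", 0.20, ("VGlut",)),
        )
        ds, truth = generate(SimConfig(n_cells=2000, seed=123, cell_types=types))
        log_normalize(ds)
        flags = classify_cells(ds, truth.catalog)
        n = ds.n_cells
        for cls in ("ACh", "GABA", "Glu"):
            planted = (truth.cell_type == cls).mean()
            se = np.sqrt(planted * (1 - planted) / n)
            assert abs(flags[cls].mean() - planted) < 3 * se
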