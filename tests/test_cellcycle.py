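import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import chi2 as chi2_dist

from vncatlas.cellcycle import (
    assign_phase,
    chi_square,
    phase_composition_test,
    score_cell_cycle,
    score_gene_set,
)
from vncatlas.preprocess import log_normalize
from vncatlas.simulate import SimConfig, generate

from conftest import make_dataset


def _ds_from_lognorm(matrix, symbols):
    counts = (np.asarray(matrix) > 0).astype(int)
    ds = make_dataset(counts, gene_symbols=symbols)
    ds.layers["lognorm"] = sp.csr_matrix(np.asarray(matrix, dtype=float))
    return ds


class TestScoreGeneSet:
    def test_set_equal_to_its_bin_scores_zero(self):
        # 2 genes, identical expression: one bin holds both; with the set =
        # the whole bin, controls are drawn from the set itself
        m = [[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]]
        ds = _ds_from_lognorm(m, ["a", "b"])
        s = score_gene_set(ds, ["a", "b"], n_bins=1, n_ctrl=10, seed=0)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_hand_computed_two_bin_example(self):
        """With every bin gene sharing one expression vector, the control
        draw is value-deterministic whatever the seed picks."""
        lo, hi = [0.1, 0.2, 0.3], [1.0, 2.0, 3.0]
        m = np.column_stack([lo, lo, lo, hi, hi, hi])
        ds = _ds_from_lognorm(m, list("abcdef"))
        # set = {d} (high bin): control from high bin always equals hi
        s = score_gene_set(ds, ["d"], n_bins=2, n_ctrl=1, seed=3)
        assert np.allclose(s, 0.0, atol=1e-12)
        # set = {d} but score against low-matched behaviour: set {a} scores 0 too
        s2 = score_gene_set(ds, ["a"], n_bins=2, n_ctrl=5, seed=9)
        assert np.allclose(s2, 0.0, atol=1e-12)

    def test_mean_difference_arithmetic(self):
        # bins: {a,b} low with identical vectors, {c,d} high identical; set
        # {c} scores c - (control == d's vector == c's) = 0; set mixing bins
        # gives the exact mean difference
        low = np.array([0.0, 0.2])
        high = np.array([2.0, 4.0])
        m = np.column_stack([low, low, high, high])
        ds = _ds_from_lognorm(m, list("abcd"))
        s = score_gene_set(ds, ["a", "c"], n_bins=2, n_ctrl=4, seed=1)
        # set mean = (low+high)/2 per cell; control mean likewise
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_gene_and_cell_order_invariance(self, sim_lognorm):
        ds, truth = sim_lognorm
        genes = truth.catalog.get("s_phase")
        a = score_gene_set(ds, genes, seed=5)
        b = score_gene_set(ds, list(reversed(genes)), seed=5)
        assert np.allclose(a, b)

    def test_planted_program_cells_score_higher(self, sim_lognorm):
        from scipy.stats import ranksums

        ds, truth = sim_lognorm
        s = score_gene_set(ds, truth.catalog.get("g2m_phase"), seed=2)
        in_phase = truth.phase == "G2M"
        assert ranksums(s[in_phase], s[~in_phase]).pvalue < 0.01
        assert s[in_phase].mean() > s[~in_phase].mean()

    def test_empty_set_errors(self, sim_lognorm):
        ds, _ = sim_lognorm
        with pytest.raises(ValueError, match="no genes"):
            score_gene_set(ds, ["NOPE1", "NOPE2"])


class TestAssignPhase:
    def test_g1_default_and_argmax(self):
        assert assign_phase([-0.2], [-0.1])[0] == "G1"
        assert assign_phase([0.5], [0.1])[0] == "S"
        assert assign_phase([0.1], [0.5])[0] == "G2M"

    def test_grid_matches_rule_oracle(self):
        grid = np.linspace(-1, 1, 21)
        s, g = np.meshgrid(grid, grid)
        s, g = s.ravel(), g.ravel()
        with pytest.warns(UserWarning, match="tied"):
            got = assign_phase(s, g)
        expect = np.array(
            ["G1" if (a <= 0 and b <= 0) else ("S" if a > b else "G2M") for a, b in zip(s, g)],
            dtype=object,
        )
        assert np.array_equal(got, expect)

    def test_never_cycling_when_both_nonpositive(self):
        rng = np.random.default_rng(0)
        s, g = -rng.random(500), -rng.random(500)
        assert set(assign_phase(s, g)) == {"G1"}


class TestChiSquare:
    def test_printed_2x2_toy(self):
        stat, p, dof = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_matches_closed_form_on_2x2_tables(self):
        """chi2 equals sum((O-E)^2/E) for integer 2x2 tables, margins <= 20."""
        checked = 0
        for a, b, c, d in itertools.product(range(0, 11, 2), repeat=4):
            table = np.array([[a, b], [c, d]])
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            if table.sum(1).max() > 20 or table.sum(0).max() > 20:
                continue
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            closed = ((table - exp) ** 2 / exp).sum()
            stat, p, dof = chi_square(table)
            assert stat == pytest.approx(closed, abs=1e-10)
            assert p == pytest.approx(chi2_dist.sf(closed, 1), abs=1e-12)
            checked += 1
        assert checked > 200

    def test_identical_composition_statistic_zero(self):
        phases = np.array(["G1", "S", "G2M"] * 20, dtype=object)
        clusters = np.repeat([0, 1], 30)
        res = phase_composition_test(phases, clusters)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)


class TestPhaseComposition:
    def test_outlier_cluster_flagged(self):
        phases = np.array(["G1"] * 90 + ["G2M"] * 30, dtype=object)
        clusters = np.array([0] * 30 + [1] * 30 + [2] * 30 + [3] * 30)
        res = phase_composition_test(phases, clusters)  # cluster 3 all G2M
        assert res.posthoc.loc[3, "p_adjusted"] < 0.05
        assert res.posthoc["p_adjusted"].idxmin() == 3

    def test_absent_phase_dropped_with_warning(self):
        phases = np.array(["G1", "S"] * 10, dtype=object)
        clusters = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="G2M"):
            res = phase_composition_test(phases, clusters)
        assert list(res.table.columns) == ["G1", "S"]

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError, match="2 clusters"):
            phase_composition_test(np.array(["G1"] * 5, object), np.zeros(5, int))


class TestEndToEndPhases:
    def test_planted_cycling_cells_recovered(self, sim_lognorm):
        ds, truth = sim_lognorm
        ds = ds.copy()
        table = score_cell_cycle(
            ds, truth.catalog.get("s_phase"), truth.catalog.get("g2m_phase"), seed=4
        )
        ct = pd.crosstab(truth.phase, table["phase"])
        # planted cycling cells are never assigned to the wrong programme
        assert ct.loc["S", "G2M"] == 0 and ct.loc["G2M", "S"] == 0
        assert ct.loc["S", "S"] / ct.loc["S"].sum() > 0.9
        assert ct.loc["G2M", "G2M"] / ct.loc["G2M"].sum() > 0.9
        assert (ds.cell_meta["phase"] == table["phase"]).all()
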