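"""Pluripotency score, rank correlations, group tests and marker detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from xcipipe.association import (
    correlate_with_activity,
    group_expression_test,
    marker_enrichment,
    pluripotency_score,
    spearman,
    xist_tsix_report,
)
from xcipipe.io import rpkm_for
from xcipipe.simulate import generate_dataset
from xcipipe.state import xci_state_table

from conftest import uniform_degree_config


class TestPluripotencyScore:
    def _expr(self, values, names):
        return pd.DataFrame(
            np.asarray(values, float)[:, None], index=names, columns=["c0"]
        )

    def test_mean_of_constants(self):
        genes = ["Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tcfcp2l1", "Prdm14"]
        score = pluripotency_score(self._expr([10] * 8, genes))
        assert score["c0"] == pytest.approx(10.0)

    def test_arithmetic_mean(self):
        genes = ["Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tcfcp2l1", "Prdm14"]
        score = pluripotency_score(self._expr([0, 0, 0, 0, 0, 0, 0, 80], genes))
        assert score["c0"] == pytest.approx(10.0)

    def test_missing_gene_warns_and_uses_rest(self):
        genes = ["Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tcfcp2l1"]
        with pytest.warns(UserWarning, match="Prdm14"):
            score = pluripotency_score(self._expr([7] * 7, genes))
        assert score["c0"] == pytest.approx(7.0)

    def test_no_genes_present_is_error(self):
        with pytest.raises(ValueError, match="none of the score genes"):
            pluripotency_score(self._expr([1.0], ["Actb"]))


class TestSpearman:
    def test_derived_rank_example(self):
        # ranks [1,2,3,4,5] vs [2,1,4,3,5]: sum d^2 = 4, r = 1 - 24/120
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_identity_gives_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5, 8.0, 0.1]
        r, p = spearman(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_input_undefined(self):
        r, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for n in [5, 8, 15, 30]:
            for _ in range(25):
                x = rng.normal(size=n)
                y = rng.normal(size=n) + 0.5 * x
                r, _ = spearman(x, y)
                rx = pd.Series(x).rank().to_numpy()
                ry = pd.Series(y).rank().to_numpy()
                oracle = np.corrcoef(rx, ry)[0, 1]
                assert r == pytest.approx(oracle, abs=1e-12)

    def test_exact_small_n_p_value(self):
        # n=4, perfect monotone: only 2 of 4! = 24 permutations reach |r| = 1
        r, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)


class TestBenjaminiHochberg:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=40))
    def test_adjustment_preserves_p_ordering(self, pvals):
        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def uniform_state():
    acs, truth = generate_dataset(
        uniform_degree_config(200, seed=31, coupling_noise_sd=0.15)
    )
    expr = rpkm_for(acs)
    res = xci_state_table(acs)
    return acs, truth, expr, res


class TestCorrelateWithActivity:
    def test_module_sign_recovery(self, uniform_state):
        acs, truth, expr, res = uniform_state
        roles = truth.genes["role"]
        pl = list(roles.index[roles == "pluripotency"])
        df = list(roles.index[roles == "differentiation"])
        table = correlate_with_activity(expr, res, gene_ids=pl + df).set_index("gene_id")
        assert (table.loc[pl, "r"] > 0).all()
        assert (table.loc[df, "r"] < 0).all()
        assert (table.loc[pl + df, "p_adj"] < 0.01).all()

    def test_per_gene_rpkm_filter_restricts_cells(self, uniform_state):
        acs, truth, expr, res = uniform_state
        gid = truth.genes.index[truth.genes["role"] == "pluripotency"][0]
        unfiltered = correlate_with_activity(expr, res, gene_ids=[gid])
        filtered = correlate_with_activity(expr, res, gene_ids=[gid],
                                           min_rpkm_filter=expr.loc[gid].median())
        assert filtered.loc[0, "n"] < unfiltered.loc[0, "n"]

    def test_internal_consistency_with_spearman(self, uniform_state):
        acs, truth, expr, res = uniform_state
        gid = truth.genes.index[truth.genes["role"] == "differentiation"][0]
        table = correlate_with_activity(expr, res, gene_ids=[gid])
        cells = res.cells.index[res.cells["activity"].notna()]
        r, p = spearman(expr.loc[gid, cells], res.cells.loc[cells, "activity"])
        assert table.loc[0, "r"] == pytest.approx(r)
        assert table.loc[0, "p"] == pytest.approx(p)


class TestGroupTest:
    def test_identical_groups_null(self):
        vals = pd.Series([5.0, 6.0, 7.0, 5.0, 6.0, 7.0],
                         index=[f"c{i}" for i in range(6)])
        groups = pd.Series(["uninitiated"] * 3 + ["ongoing"] * 3, index=vals.index)
        res = group_expression_test(vals, groups)
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_clear_difference_significant(self):
        vals = pd.Series([10.0, 11.0, 12.0, 1.0, 2.0, 3.0],
                         index=[f"c{i}" for i in range(6)])
        groups = pd.Series(["uninitiated"] * 3 + ["completed"] * 3, index=vals.index)
        res = group_expression_test(vals, groups)
        assert res["p"] < 0.01
        assert res["mean_uninitiated"] > res["mean_initiated"]

    def test_single_cell_group_is_error(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = pd.Series(["uninitiated", "ongoing", "ongoing"], index=vals.index)
        with pytest.raises(ValueError, match=">= 2 cells"):
            group_expression_test(vals, groups)

    def test_asynchrony_on_synthetic_data(self, uniform_state):
        # noisy coupling: some completed-XCI cells still score above the
        # uninitiated-group median pluripotency expression
        acs, truth, expr, res = uniform_state
        score = pluripotency_score(expr, gene_names=acs.gene_names())
        groups = res.cells["xci_group"]
        uni_median = score[groups[groups == "uninitiated"].index].median()
        completed = score[groups[groups == "completed"].index]
        assert (completed > uni_median).any()


class TestMarkerEnrichment:
    def _expr(self, means, n_per=5, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        cols, vals, conds = [], [], []
        for ci, m in enumerate(means):
            for j in range(n_per):
                cols.append(f"c{ci}_{j}")
                vals.append(m + rng.normal(0, noise))
                conds.append(f"cond{ci}")
        expr = pd.DataFrame([vals], index=["g0"], columns=cols)
        return expr, pd.Series(conds, index=cols)

    def test_strong_enrichment_detected(self):
        expr, conds = self._expr([100, 10, 10, 10])
        table = marker_enrichment(expr, conds)
        assert table.loc[0, "enriched_condition"] == "cond0"

    def test_insufficient_fold_change_not_enriched(self):
        expr, conds = self._expr([100, 30, 10, 10])
        table = marker_enrichment(expr, conds)
        assert table.loc[0, "enriched_condition"] is None

    def test_flat_means_not_enriched(self):
        expr, conds = self._expr([10, 10, 10, 10])
        table = marker_enrichment(expr, conds)
        assert table.loc[0, "enriched_condition"] is None

    def test_label_permutation_permutes_assignment(self):
        expr, conds = self._expr([100, 10, 10, 10])
        mapping = {"cond0": "condX", "cond1": "cond0", "cond2": "cond1", "cond3": "cond2"}
        table = marker_enrichment(expr, conds.map(mapping))
        assert table.loc[0, "enriched_condition"] == "condX"

    def test_degenerate_condition_size_is_error(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=["a", "b", "c"])
        conds = pd.Series(["x", "x", "y"], index=expr.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            marker_enrichment(expr, conds)


class TestXistTsix:
    def test_xist_tracks_initiation(self, preset_data):
        acs, truth, expr = preset_data
        res = xci_state_table(acs)
        names = acs.gene_names()
        xist_id = [g for g in names.index if names[g] == "Xist"][0]
        groups = res.cells["xci_group"]
        initiated = groups[groups.isin(["ongoing", "completed"])].index
        uninitiated = groups[groups == "uninitiated"].index
        assert (expr.loc[xist_id, initiated].mean()
                > expr.loc[xist_id, uninitiated].mean())

    def test_report_structure_and_degenerate_male_comparison(self, preset_data):
        acs, truth, expr = preset_data
        res = xci_state_table(acs)
        report = xist_tsix_report(expr, res, acs.cells, gene_names=acs.gene_names())
        assert {"r_xist_tsix", "p_female_vs_male_xist"} <= set(report.columns)
        # female Xist expressed, male Xist silent -> significant difference
        epi = report[(report["base_condition"] == "Epi") & (report["sex"] == "F")]
        assert epi["p_female_vs_male_xist"].iloc[0] < 0.01

    def test_missing_gene_named_in_error(self, preset_data):
        acs, _, expr = preset_data
        res = xci_state_table(acs)
        with pytest.raises(ValueError, match="NotAGene"):
            xist_tsix_report(expr, res, acs.cells, gene_names=acs.gene_names(),
                             xist="NotAGene")
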