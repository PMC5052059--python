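"""Activity index, XCI grouping, window profiles and escapee detection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xcipipe.simulate import ConditionSpec, SimConfig, generate_dataset
from xcipipe.state import (
    activity_from_fraction,
    classify_xci,
    detect_escapees,
    maternal_fraction,
    maternal_fraction_per_cell,
    window_ratio_profile,
    xci_state_table,
)

from conftest import make_acs


class TestMaternalFraction:
    def test_arithmetic(self):
        acs = make_acs([[75]], [[25]], chromosomes=["X"])
        f, n = maternal_fraction(acs, "c0")
        assert f == pytest.approx(0.75) and n == 100

    def test_symmetry_at_balance(self):
        acs = make_acs([[50]], [[50]], chromosomes=["X"])
        assert maternal_fraction(acs, "c0")[0] == pytest.approx(0.5)

    def test_zero_denominator_flagged_nan(self):
        acs = make_acs([[0]], [[0]], chromosomes=["X"])
        f, n = maternal_fraction(acs, "c0")
        assert np.isnan(f) and n == 0

    def test_simulated_male_fraction_is_one(self):
        cfg = SimConfig(
            conditions=[ConditionSpec(name="m", sex="M")],
            n_cells_per_condition=5, n_x_genes=30, seed=4,
        )
        acs, _ = generate_dataset(cfg)
        frac = maternal_fraction_per_cell(acs)["fraction"]
        assert np.allclose(frac, 1.0)


class TestActivity:
    @pytest.mark.parametrize("f, a", [(0.5, 2.0), (1.0, 1.0), (0.0, 1.0), (0.8, 1.25)])
    def test_known_values(self, f, a):
        assert activity_from_fraction(f) == pytest.approx(a)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            activity_from_fraction(1.2)
        with pytest.raises(ValueError):
            activity_from_fraction(-0.1)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetric_and_bounded(self, f):
        a = activity_from_fraction(f)
        assert a == pytest.approx(activity_from_fraction(1.0 - f))
        assert 1.0 <= a <= 2.0

    def test_monotone_decreasing_in_imbalance(self):
        f = np.linspace(0.5, 1.0, 101)
        a = activity_from_fraction(f)
        assert (np.diff(a) < 0).all()


class TestClassify:
    @pytest.mark.parametrize(
        "a, group",
        [
            (1.95, "uninitiated"),
            (1.5, "ongoing"),
            (1.8, "ongoing"),  # boundary belongs to the lower group
            (1.2, "completed"),
            (1.0, "completed"),
            (2.0, "uninitiated"),
        ],
    )
    def test_interval_conventions(self, a, group):
        assert classify_xci(a) == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_xci(2.3)

    def test_partitions_activity_range(self):
        grid = np.linspace(1.0, 2.0, 10_001)
        groups = classify_xci(grid)
        assert set(groups) == {"uninitiated", "ongoing", "completed"}
        # every value maps to exactly one group (total function on the grid)
        assert len(groups) == len(grid)

    def test_custom_bounds_validated(self):
        with pytest.raises(ValueError, match="bounds"):
            classify_xci(1.5, bounds=(1.9, 1.4))


class TestStateTable:
    def test_all_balanced_cells_uninitiated(self):
        cfg = SimConfig(
            conditions=[ConditionSpec(name="f", sex="F", degree=0.0)],
            n_cells_per_condition=10, n_x_genes=60, mean_depth=40, seed=6,
        )
        acs, _ = generate_dataset(cfg)
        res = xci_state_table(acs)
        assert (res.cells["xci_group"] == "uninitiated").all()
        summary = res.condition_summary
        pct = summary.loc[summary["xci_group"] == "uninitiated", "percent"]
        assert pct.iloc[0] == pytest.approx(100.0)

    def test_insufficient_reads_flagged(self):
        acs = make_acs([[3], [0]], [[2], [0]], chromosomes=["X", "X"])
        res = xci_state_table(acs, min_informative_reads=50)
        assert res.cells.loc["c0", "xci_group"] == "insufficient"

    def test_no_female_cells_is_error(self):
        acs = make_acs([[5]], [[5]], chromosomes=["X"], sex=["M"])
        with pytest.raises(ValueError, match="female"):
            xci_state_table(acs)

    def test_inactive_allele_is_lower_expressed(self):
        acs = make_acs(
            [[80, 20, 50]], [[20, 80, 50]], chromosomes=["X"],
        )
        res = xci_state_table(acs, min_informative_reads=10)
        assert res.cells.loc["c0", "inactive_allele"] == "paternal"
        assert res.cells.loc["c1", "inactive_allele"] == "maternal"
        assert res.cells.loc["c2", "inactive_allele"] == "undetermined"

    def test_skew_test_counts_initiated_only(self, preset_data):
        acs, truth, _ = preset_data
        res = xci_state_table(acs)
        skew = res.skew_tests.set_index("condition")
        for cond, row in skew.iterrows():
            assert row["n_maternal_inactive"] + row["n_paternal_inactive"] <= row["n_initiated"]
            if row["n_initiated"] > 0:
                assert 0 <= row["binomial_p"] <= 1


def _brute_force_windows(acs, cells, inactive_allele, window):
    """Independent recomputation: per-window loop over raw count matrices."""
    x = acs.genes_on("X")
    names = acs.genes.loc[x, "gene_name"]
    x = x[~names.isin(["Xist", "Tsix"])]
    order = acs.genes.loc[x, "start"].sort_values().index
    keep = []
    for g in order:
        tot = sum(acs.maternal.loc[g, c] + acs.paternal.loc[g, c] for c in cells)
        if tot > 0:
            keep.append(g)
    ratios = []
    for i in range(0, max(len(keep) - window + 1, 0)):
        ia = aa = 0
        for g in keep[i:i + window]:
            for c in cells:
                m, p = acs.maternal.loc[g, c], acs.paternal.loc[g, c]
                if inactive_allele[c] in ("maternal", "undetermined"):
                    ia, aa = ia + m, aa + p
                else:
                    ia, aa = ia + p, aa + m
        ratios.append(ia / aa if aa > 0 else np.nan)
    return ratios


class TestWindowProfile:
    def test_single_window_sums(self):
        inactive = [0, 1, 0, 2, 0, 1, 0, 0, 1, 0]
        active = [10, 8, 12, 9, 11, 7, 10, 9, 8, 6]
        # single cell whose inactive allele is maternal (f < 0.5)
        acs = make_acs(
            np.array(inactive)[:, None], np.array(active)[:, None],
            chromosomes=["X"] * 10,
        )
        res = xci_state_table(acs, min_informative_reads=10)
        prof = window_ratio_profile(acs, res, window_genes=10)
        assert len(prof) == 1
        assert prof.loc[0, "inactive_sum"] == 5
        assert prof.loc[0, "active_sum"] == 90
        assert prof.loc[0, "ratio"] == pytest.approx(5 / 90)

    def test_matches_brute_force(self):
        cfg = SimConfig(
            conditions=[ConditionSpec(name="f", sex="F",
                                      weights=(0.3, 0.4, 0.3), spread=1.0)],
            n_cells_per_condition=20, n_x_genes=15, n_escapees=2,
            mean_depth=15, dropout_scale=3.0, seed=13,
        )
        acs, _ = generate_dataset(cfg)
        res = xci_state_table(acs, min_informative_reads=10)
        cells = list(res.cells.index)
        prof = window_ratio_profile(acs, res, cells, window_genes=10)
        expected = _brute_force_windows(acs, cells, res.cells["inactive_allele"], 10)
        assert len(prof) == len(expected)
        for got, want in zip(prof["ratio"], expected):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_fewer_genes_than_window_single_window(self):
        acs = make_acs([[4], [6]], [[1], [2]], chromosomes=["X", "X"])
        res = xci_state_table(acs, min_informative_reads=5)
        with pytest.warns(UserWarning, match="single whole-chromosome"):
            prof = window_ratio_profile(acs, res, window_genes=10)
        assert len(prof) == 1 and prof.loc[0, "n_genes"] == 2

    def test_completed_without_escapees_all_zero(self):
        cfg = SimConfig(
            conditions=[ConditionSpec(name="f", sex="F", degree=1.0)],
            n_cells_per_condition=15, n_x_genes=30, n_escapees=0,
            mean_depth=40, seed=17,
        )
        acs, _ = generate_dataset(cfg)
        res = xci_state_table(acs)
        prof = window_ratio_profile(acs, res)
        assert (prof["ratio"].dropna() == 0).all()
        assert prof["inactive_sum"].sum() == 0


class TestEscapees:
    def _completed_data(self, n_escapees, seed=19):
        cfg = SimConfig(
            conditions=[ConditionSpec(name="f", sex="F", degree=1.0)],
            n_cells_per_condition=50, n_x_genes=40, n_escapees=n_escapees,
            escapee_retention=0.5, mean_depth=40, seed=seed,
        )
        return generate_dataset(cfg)

    def test_true_escapees_flagged(self):
        acs, truth = self._completed_data(3)
        res = xci_state_table(acs)
        report = detect_escapees(acs, res)
        true_esc = set(truth.genes.index[truth.genes["is_escapee"]])
        assert set(report.index[report["escapee"]]) == true_esc

    def test_no_escapees_none_flagged(self):
        acs, _ = self._completed_data(0)
        res = xci_state_table(acs)
        report = detect_escapees(acs, res)
        assert not report["escapee"].any()

    def test_degenerate_thresholds_flag_every_expressed_gene(self):
        acs, _ = self._completed_data(2)
        res = xci_state_table(acs)
        report = detect_escapees(acs, res, min_ratio=0.0, min_cell_fraction=0.0)
        expressed = report["n_cells_expressed"] > 0
        assert report.loc[expressed, "escapee"].all()

    def test_requires_completed_cells(self):
        acs = make_acs([[50]], [[50]], chromosomes=["X"])
        res = xci_state_table(acs, min_informative_reads=10)
        with pytest.raises(ValueError, match="completed"):
            detect_escapees(acs, res)
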