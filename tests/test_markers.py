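"""Marker kinetics: log fold change, cohort means, cell ratios, paired t tests."""

import numpy as np
import pandas as pd
import pytest

from repdyn import (
    AnalyteMatrix,
    AnalyteSpec,
    SimulationConfig,
    cell_ratio,
    cohort_mean_logfc,
    log_fold_change,
    paired_t,
    simulate_analytes,
)

from _oracles import t_sf_oracle


def _matrix(rows, llod=None):
    df = pd.DataFrame(rows, columns=["subject", "analyte", "timepoint", "value"])
    return AnalyteMatrix.from_long(df, llod=llod)


@pytest.fixture
def simple_matrix():
    rows = []
    for subj, scale in (("S1", 1.0), ("S2", 2.0)):
        for tp, mult in (("Pre", 1.0), ("PI", 10.0), ("PC", 100.0)):
            rows.append((subj, "IFNg", tp, 10.0 * scale * mult))
    return _matrix(rows)


class TestLogFoldChange:
    def test_baseline_column_is_zero_and_tenfold_is_one(self, simple_matrix):
        logfc, n_floored = log_fold_change(simple_matrix, baseline="Pre", base=10)
        vals = logfc.values
        assert n_floored == 0
        assert np.allclose(vals.loc[:, ("IFNg", "Pre")], 0.0)
        assert np.allclose(vals.loc[:, ("IFNg", "PI")], 1.0)
        assert np.allclose(vals.loc[:, ("IFNg", "PC")], 2.0)

    def test_exponentiation_recovers_the_ratio(self, simple_matrix):
        logfc, _ = log_fold_change(simple_matrix, baseline="Pre", base=2)
        ratio = 2.0 ** logfc.values.loc["S2", ("IFNg", "PI")]
        assert ratio == pytest.approx(10.0, abs=1e-9)

    def test_zero_without_llod_is_missing_not_minus_inf(self):
        m = _matrix([("S1", "A", "Pre", 5.0), ("S1", "A", "PC", 0.0)])
        logfc, _ = log_fold_change(m)
        assert np.isnan(logfc.values.loc["S1", ("A", "PC")])

    def test_below_llod_values_are_floored_and_counted(self):
        m = _matrix(
            [("S1", "A", "Pre", 0.1), ("S1", "A", "PC", 8.0),
             ("S2", "A", "Pre", 2.0), ("S2", "A", "PC", 8.0)],
            llod={"A": 2.0},
        )
        logfc, n_floored = log_fold_change(m, base=2)
        assert n_floored == 1
        # S1 baseline floored 0.1 -> 2.0, so log2(8/2) = 2
        assert logfc.values.loc["S1", ("A", "PC")] == pytest.approx(2.0)

    def test_missing_baseline_propagates_missing(self):
        m = _matrix([("S1", "A", "PI", 5.0), ("S2", "A", "Pre", 1.0), ("S2", "A", "PI", 2.0)])
        logfc, _ = log_fold_change(m)
        assert np.isnan(logfc.values.loc["S1", ("A", "PI")])
        assert not np.isnan(logfc.values.loc["S2", ("A", "PI")])

    def test_simulated_cohort_recovers_true_effect(self):
        cfg = SimulationConfig(
            seed=17, n_subjects=30,
            analytes={"X": AnalyteSpec(effects={"PC": 10.0 ** 0.5}, noise_log10_sd=0.2)},
        )
        matrix, _ = simulate_analytes(cfg)
        logfc, _ = log_fold_change(matrix, baseline="Pre", base=10)
        col = logfc.values.loc[:, ("X", "PC")]
        se = col.std(ddof=1) / np.sqrt(len(col))
        assert abs(col.mean() - 0.5) < 2 * se + 1e-9

    def test_zero_noise_gives_exact_log_effect(self):
        cfg = SimulationConfig(
            seed=1, n_subjects=5,
            analytes={"X": AnalyteSpec(effects={"PC": 3.0}, noise_log10_sd=0.0,
                                       baseline_log10_sd=0.4)},
        )
        matrix, _ = simulate_analytes(cfg)
        logfc, _ = log_fold_change(matrix, baseline="Pre", base=10)
        assert np.allclose(
            logfc.values.loc[:, ("X", "PC")], np.log10(3.0), atol=1e-9
        )


class TestCohortMean:
    def test_single_subject_means_are_its_values(self):
        m = _matrix([("S1", "A", "Pre", 4.0), ("S1", "A", "PC", 8.0)])
        logfc, _ = log_fold_change(m, base=2)
        means, ns = cohort_mean_logfc(logfc)
        assert means.loc["A", "PC"] == pytest.approx(1.0)
        assert ns.loc["A", "PC"] == 1

    def test_symmetric_logfc_averages_to_zero(self):
        m = _matrix(
            [("S1", "A", "Pre", 1.0), ("S1", "A", "PC", 2.0),
             ("S2", "A", "Pre", 1.0), ("S2", "A", "PC", 0.5)]
        )
        logfc, _ = log_fold_change(m, base=2)
        means, ns = cohort_mean_logfc(logfc)
        assert means.loc["A", "PC"] == pytest.approx(0.0, abs=1e-12)
        assert ns.loc["A", "PC"] == 2

    def test_all_missing_cell_reports_n_zero(self):
        m = _matrix(
            [("S1", "A", "Pre", 1.0), ("S1", "A", "PC", 0.0),
             ("S2", "A", "Pre", 1.0), ("S2", "A", "PC", 0.0)]
        )
        logfc, _ = log_fold_change(m)
        means, ns = cohort_mean_logfc(logfc)
        assert np.isnan(means.loc["A", "PC"])
        assert ns.loc["A", "PC"] == 0

    def test_effect_at_pc_peaks_at_pc(self):
        cfg = SimulationConfig(
            seed=23, n_subjects=20,
            analytes={"X": AnalyteSpec(effects={"PC": 3.0}, noise_log10_sd=0.05)},
        )
        matrix, truth = simulate_analytes(cfg)
        logfc, _ = log_fold_change(matrix)
        means, _ = cohort_mean_logfc(logfc)
        assert means.loc["X"].idxmax() == "PC"
        assert truth.analyte_effects["X"] == {"PC": 3.0}


class TestCellRatio:
    def test_teff_treg_style_ratio(self):
        m = _matrix(
            [("S1", "CD8", "Pre", 20.0), ("S1", "Treg", "Pre", 5.0)]
        )
        r = cell_ratio(m, "CD8", "Treg")
        assert r.values.loc["S1", "Pre"] == pytest.approx(4.0)

    def test_identical_analytes_give_one(self):
        m = _matrix([("S1", "CD8", "Pre", 7.0), ("S1", "Treg", "Pre", 7.0)])
        assert cell_ratio(m, "CD8", "Treg").values.loc["S1", "Pre"] == pytest.approx(1.0)

    def test_zero_denominator_yields_missing_not_inf(self):
        m = _matrix([("S1", "CD8", "Pre", 7.0), ("S1", "Treg", "Pre", 0.0)])
        assert np.isnan(cell_ratio(m, "CD8", "Treg").values.loc["S1", "Pre"])

    def test_declining_denominator_gives_monotone_ratio(self):
        rows = []
        for tp, den in (("Pre", 8.0), ("PI", 4.0), ("PC", 2.0), ("PS", 1.0)):
            rows += [("S1", "CD8", tp, 16.0), ("S1", "PD1hi", tp, den)]
        r = cell_ratio(_matrix(rows), "CD8", "PD1hi").values.loc["S1"]
        ordered = [r[tp] for tp in ("Pre", "PI", "PC", "PS")]
        assert ordered == sorted(ordered)


class TestPairedT:
    def test_identical_columns_give_t_zero_p_one(self):
        rows = []
        for i, v in enumerate((3.0, 5.0, 7.0)):
            rows += [(f"S{i}", "A", "Pre", v), (f"S{i}", "A", "PC", v)]
        res = paired_t(_matrix(rows), "PC", "Pre")
        assert res.loc["A", "t"] == 0.0
        assert res.loc["A", "p"] == 1.0

    def test_constant_nonzero_differences_flagged_degenerate(self):
        rows = []
        for i in range(4):
            rows += [(f"S{i}", "A", "Pre", 1.0), (f"S{i}", "A", "PC", 2.0)]
        res = paired_t(_matrix(rows), "PC", "Pre")
        assert bool(res.loc["A", "degenerate"])
        assert np.isnan(res.loc["A", "p"])

    def test_textbook_hand_computation(self):
        # differences 2.1, 1.8, 2.4, 2.0, 1.7: mean 2.0, sd sqrt(0.075)
        diffs = [2.1, 1.8, 2.4, 2.0, 1.7]
        rows = []
        for i, d in enumerate(diffs):
            rows += [(f"S{i}", "A", "Pre", 1.0), (f"S{i}", "A", "PC", 1.0 + d)]
        res = paired_t(_matrix(rows), "PC", "Pre")
        t_expected = 2.0 / np.sqrt(0.075 / 5)
        assert res.loc["A", "t"] == pytest.approx(t_expected, rel=1e-9)
        # tolerance bounded by the oracle's quadrature precision
        assert res.loc["A", "p"] == pytest.approx(
            2 * t_sf_oracle(t_expected, df=4), rel=2e-5
        )
        assert res.loc["A", "n"] == 5

    def test_subjects_with_missing_member_excluded_pairwise(self):
        rows = [
            ("S1", "A", "Pre", 1.0), ("S1", "A", "PC", 2.0),
            ("S2", "A", "Pre", 1.0),                           # no PC value
            ("S3", "A", "Pre", 1.0), ("S3", "A", "PC", 3.0),
        ]
        res = paired_t(_matrix(rows), "PC", "Pre")
        assert res.loc["A", "n"] == 2

    def test_fewer_than_two_pairs_is_missing_with_n_reported(self):
        rows = [("S1", "A", "Pre", 1.0), ("S1", "A", "PC", 2.0)]
        res = paired_t(_matrix(rows), "PC", "Pre")
        assert res.loc["A", "n"] == 1
        assert np.isnan(res.loc["A", "p"])

    def test_antisymmetric_in_the_label_pair(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            rows += [(f"S{i}", "A", "Pre", float(rng.uniform(1, 5))),
                     (f"S{i}", "A", "PC", float(rng.uniform(1, 5)))]
        m = _matrix(rows)
        fwd = paired_t(m, "PC", "Pre")
        rev = paired_t(m, "Pre", "PC")
        assert rev.loc["A", "t"] == pytest.approx(-fwd.loc["A", "t"], rel=1e-12)
        assert rev.loc["A", "p"] == pytest.approx(fwd.loc["A", "p"], rel=1e-12)


class TestMatrixValidation:
    def test_negative_values_rejected(self):
        df = pd.DataFrame(
            [("S1", "A", "Pre", -1.0)], columns=["subject", "analyte", "timepoint", "value"]
        )
        with pytest.raises(ValueError, match=">= 0"):
            AnalyteMatrix.from_long(df)

    def test_unknown_timepoint_rejected(self):
        df = pd.DataFrame(
            [("S1", "A", "Week9", 1.0)], columns=["subject", "analyte", "timepoint", "value"]
        )
        with pytest.raises(ValueError, match="Week9"):
            AnalyteMatrix.from_long(df)
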