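"""Histogram modeling, extra-SS F test and nested hierarchical testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qfish3d import (
    CellRecord,
    compare_fits_f_test,
    detection_coverage,
    fit_histogram,
    nested_test,
    pooled_t_test,
    simulate_nested_values,
    summarize_cells,
)
from qfish3d.quantify import TelomereFeatures


class TestFitHistogram:
    def test_gaussian_parameters_recovered(self, rng):
        vals = rng.normal(100.0, 10.0, size=5000)
        fit = fit_histogram(vals, "gaussian", robust=True)
        assert fit.mu == pytest.approx(100.0, abs=1.0)
        assert fit.sigma == pytest.approx(10.0, abs=1.0)

    def test_lognormal_parameters_recovered(self, rng):
        vals = 50.0 * np.exp(rng.standard_normal(5000) * np.log(1.6))
        fit = fit_histogram(vals, "lognormal")
        assert fit.geo_mean == pytest.approx(50.0, rel=0.05)
        assert fit.geo_sd == pytest.approx(1.6, rel=0.05)
        assert fit.r2 > 0.95

    def test_gaussian_beats_lognormal_on_symmetric_data(self, rng):
        vals = rng.normal(100.0, 10.0, size=5000)
        g = fit_histogram(vals, "gaussian")
        l = fit_histogram(vals, "lognormal")
        assert g.r2 >= l.r2

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_histogram([5.0] * 50)
        with pytest.raises(ValueError):
            fit_histogram(np.arange(10.0))  # too few values
        with pytest.raises(ValueError):
            fit_histogram(np.linspace(-1, 1, 50), "lognormal")


class TestCompareFitsFTest:
    def test_identical_datasets_give_p_one(self, rng):
        a = 50.0 * np.exp(rng.standard_normal(800) * np.log(1.5))
        assert compare_fits_f_test(a, a.copy()) == pytest.approx(1.0)

    def test_twofold_geomean_difference_detected(self, rng):
        a = 50.0 * np.exp(rng.standard_normal(2000) * np.log(1.6))
        b = 100.0 * np.exp(rng.standard_normal(2000) * np.log(1.6))
        assert compare_fits_f_test(a, b) < 0.001

    def test_null_rarely_rejects(self):
        above = 0
        n_seeds = 30
        for s in range(n_seeds):
            g = np.random.default_rng(500 + s)
            a = 50.0 * np.exp(g.standard_normal(1000) * np.log(1.5))
            b = 50.0 * np.exp(g.standard_normal(1000) * np.log(1.5))
            if compare_fits_f_test(a, b) > 0.05:
                above += 1
        assert above >= int(0.8 * n_seeds)


class TestNestedTest:
    def test_all_equal_repeated_values_give_p_one(self):
        groups = {"A": [[5.0, 5.0, 5.0]] * 3, "B": [[5.0, 5.0, 5.0]] * 3}
        res = nested_test(groups, transform="none")
        assert res.p_group == 1.0

    def test_single_cell_condition_raises_pseudo_replication(self):
        groups = {"A": [[1.0, 2.0]], "B": [[1.0, 2.0], [2.0, 3.0]]}
        with pytest.raises(ValueError, match="pseudo-replicat"):
            nested_test(groups, transform="none")

    def test_effect_recovered_on_lognormal_data(self):
        effects = []
        for s in range(15):
            g = simulate_nested_values(9, 8, 90, effect_pct=18.0, seed=3000 + s)
            g["B"] = [v for v in g["B"]]
            res = nested_test({"A": g["A"], "B": g["B"]})
            effects.append(res.effect_pct)
        assert np.median(effects) == pytest.approx(-18.0, abs=4.0)

    def test_invariant_to_cell_order_and_positive_scaling(self):
        g = simulate_nested_values(4, 4, 30, effect_pct=10.0, seed=9)
        base = nested_test(g)
        flipped = {"A": list(reversed(g["A"])), "B": list(reversed(g["B"]))}
        scaled = {k: [np.asarray(c) * 37.5 for c in v] for k, v in g.items()}
        assert nested_test(flipped).p_group == pytest.approx(base.p_group)
        assert nested_test(scaled).p_group == pytest.approx(base.p_group)
        assert nested_test(scaled).effect_pct == pytest.approx(base.effect_pct)

    def test_nested_less_anticonservative_than_pooled(self):
        """With strong between-cell variance the pooled t-test treats
        pseudo-replicates as independent and yields smaller p-values."""
        wins = 0
        n = 40
        for s in range(n):
            g = simulate_nested_values(
                5, 5, 40, between_geo_sd=1.4, within_geo_sd=1.3, seed=7000 + s
            )
            if pooled_t_test(g) < nested_test(g).p_group:
                wins += 1
        assert wins >= int(0.95 * n)

    def test_type_one_error_near_nominal(self):
        rej = 0
        n = 200
        for s in range(n):
            g = simulate_nested_values(9, 8, 30, effect_pct=0.0, seed=40_000 + s)
            if nested_test(g).p_group <= 0.05:
                rej += 1
        assert 0.02 <= rej / n <= 0.09

    @given(factor=st.floats(0.1, 10.0))
    def test_log10_absorbs_multiplicative_shifts(self, factor):
        g = simulate_nested_values(3, 3, 20, seed=55)
        scaled = {k: [np.asarray(c) * factor for c in v] for k, v in g.items()}
        assert nested_test(scaled).p_group == pytest.approx(
            nested_test(g).p_group, rel=1e-9
        )


def _record(cell_id, phase, densities):
    feats = [
        TelomereFeatures(
            spot_id=i, z_nm=0, y_nm=0, x_nm=0, n_voxels=20, peak_counts=30,
            brightness_peak=40.0, fwhm_x_nm=130.0, fwhm_y_nm=132.0,
            signal_density=d, r2_x=0.9, r2_y=0.9, quality_flag="both_fits",
        )
        for i, d in enumerate(densities)
    ]
    return CellRecord(cell_id, phase, feats)


class TestSummarizeCells:
    def test_coverage_worked_examples(self):
        assert round(detection_coverage(207.0, 312)) == 66
        assert round(detection_coverage(89.9, 156)) == 58

    def test_single_cell_has_no_sd_or_cv(self):
        df = summarize_cells([_record("c1", "interphase", [1.0, 2.0])])
        row = df.loc["interphase"]
        assert row["sd_count"] is None and row["cv_count_pct"] is None

    def test_counts_and_coverage_table(self):
        recs = [
            _record("m1", "M-phase", [1.0] * 207),
            _record("m2", "M-phase", [1.0] * 207),
            _record("i1", "interphase", [1.0] * 90),
            _record("i2", "interphase", [1.0] * 90),
        ]
        df = summarize_cells(recs, {"M-phase": 312, "interphase": 156})
        assert df.loc["M-phase", "mean_count"] == 207
        assert round(df.loc["M-phase", "coverage_pct"]) == 66
        assert round(df.loc["interphase", "coverage_pct"]) == 58
        assert df.loc["interphase", "geomean_density"] == pytest.approx(1.0)
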