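"""Calibration fitting, drift and error propagation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import navdrop as nd


def normal_equations_fit(c, e):
    """Independent least-squares oracle: solve X'X beta = X'y directly."""
    X = np.column_stack([np.asarray(c, float), np.ones(len(c))])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(e, float))
    return beta[0], beta[1]


class TestFitCalibration:
    def test_collinear_recovery(self):
        c = np.linspace(100, 140, 41)
        model = nd.fit_calibration(np.column_stack([c, 0.5 * c - 50.0]))
        assert model.slope_mm_per_pf == pytest.approx(0.5, rel=1e-12)
        assert model.intercept_mm == pytest.approx(-50.0, rel=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_point_input(self):
        model = nd.fit_calibration([(100.0, 0.0), (140.0, 20.0)])
        assert model.slope_mm_per_pf == pytest.approx(0.5)
        assert model.n_points == 2

    def test_outlier_matches_normal_equations_oracle(self):
        c = np.linspace(100, 140, 20)
        e = 0.5 * c - 50.0
        e[7] += 3.0  # one off-line point
        model = nd.fit_calibration(np.column_stack([c, e]))
        slope, intercept = normal_equations_fit(c, e)
        assert model.slope_mm_per_pf == pytest.approx(slope, rel=1e-12)
        assert model.intercept_mm == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_sweep_rejected(self):
        with pytest.raises(nd.DegenerateSweepError):
            nd.fit_calibration([(100.0, 0.0), (100.0, 5.0)])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6), st.integers(3, 50))
    def test_random_sweeps_match_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        c = 100.0 + np.cumsum(rng.uniform(0.1, 2.0, n))
        e = rng.normal(0.45, 0.05) * c + rng.normal(-45, 5) + rng.normal(0, 0.2, n)
        model = nd.fit_calibration(np.column_stack([c, e]))
        slope, intercept = normal_equations_fit(c, e)
        assert model.slope_mm_per_pf == pytest.approx(slope, rel=1e-10)
        assert model.intercept_mm == pytest.approx(intercept, rel=1e-10)
        assert 0.0 <= model.r_squared <= 1.0

    def test_r2_is_one_iff_collinear(self):
        c = np.linspace(100, 140, 10)
        on_line = nd.fit_calibration(np.column_stack([c, 0.3 * c + 1.0]))
        assert on_line.r_squared == pytest.approx(1.0, abs=1e-12)
        e = 0.3 * c + 1.0
        e[0] += 0.5
        off_line = nd.fit_calibration(np.column_stack([c, e]))
        assert off_line.r_squared < 1.0


class TestTwoPoint:
    def test_line_through_points(self):
        model = nd.two_point_calibrate((100.0, 0.0), (140.0, 20.0))
        assert model.slope_mm_per_pf == pytest.approx(0.5)
        assert model.intercept_mm == pytest.approx(-50.0)
        assert model.r_squared is None

    def test_argument_order_symmetry(self):
        a = nd.two_point_calibrate((100.0, 0.0), (140.0, 20.0))
        b = nd.two_point_calibrate((140.0, 20.0), (100.0, 0.0))
        assert a.slope_mm_per_pf == b.slope_mm_per_pf
        assert a.intercept_mm == b.intercept_mm

    def test_agrees_with_full_fit(self):
        pts = [(103.0, 1.2), (131.5, 15.9)]
        tp = nd.two_point_calibrate(*pts)
        ls = nd.fit_calibration(pts)
        assert tp.slope_mm_per_pf == pytest.approx(ls.slope_mm_per_pf, rel=1e-12)

    def test_identical_capacitances_rejected(self):
        with pytest.raises(nd.DegenerateSweepError):
            nd.two_point_calibrate((100.0, 0.0), (100.0, 20.0))


class TestApplyCalibration:
    def test_constant_at_reference_maps_to_zero(self):
        model = nd.CalibrationModel(slope_mm_per_pf=0.5, intercept_mm=-50.0,
                                    r_squared=None, n_points=2)
        series = nd.StrainSeries(t_s=np.arange(10) / 200.0,
                                 capacitance_pF=np.full(10, 100.0))
        out = nd.apply_calibration(series, model)
        assert np.allclose(out.elongation_mm, 0.0)
        assert np.array_equal(out.t_s, series.t_s)

    def test_unit_capacitance_step(self):
        model = nd.CalibrationModel(slope_mm_per_pf=0.5, intercept_mm=-50.0,
                                    r_squared=None, n_points=2)
        series = nd.StrainSeries(t_s=np.array([0.0, 0.005]),
                                 capacitance_pF=np.array([100.0, 101.0]))
        out = nd.apply_calibration(series, model)
        assert out.elongation_mm[1] - out.elongation_mm[0] == pytest.approx(0.5)

    def test_roundtrip_with_simulator(self, default_sensor, bench_model):
        """Calibrated elongation inverts the simulated transduction to
        within one quantization step."""
        elong = np.linspace(0.0, 15.0, 301)
        cap = nd.elongation_to_capacitance(elong, default_sensor)
        series = nd.StrainSeries(t_s=np.arange(301) / 200.0, capacitance_pF=cap)
        out = nd.apply_calibration(series, bench_model)
        tol = default_sensor.quant_pf * abs(default_sensor.slope_mm_per_pf)
        assert np.max(np.abs(out.elongation_mm - elong)) <= tol + 1e-9


class TestDrift:
    def test_identical_models_zero_drift(self):
        m = nd.two_point_calibrate((100.0, 0.0), (140.0, 20.0))
        assert nd.slope_drift(m, m) == 0.0

    @pytest.mark.parametrize("s_a, s_b, expected", [
        (2.00, 2.05, 2.5),   # the typical bench test-retest magnitude
        (0.50, 0.52, 4.0),   # the maximal drift seen over months of use
    ])
    def test_drift_direct_evaluation(self, s_a, s_b, expected):
        mk = lambda s: nd.CalibrationModel(slope_mm_per_pf=s, intercept_mm=0.0,
                                           r_squared=None, n_points=2)
        assert nd.slope_drift(mk(s_a), mk(s_b)) == pytest.approx(expected)

    def test_drift_invariant_to_common_rescaling(self):
        mk = lambda s: nd.CalibrationModel(slope_mm_per_pf=s, intercept_mm=0.0,
                                           r_squared=None, n_points=2)
        d1 = nd.slope_drift(mk(0.5), mk(0.52))
        d2 = nd.slope_drift(mk(5.0), mk(5.2))
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestDriftToAccuracy:
    def test_four_percent_on_10mm_is_0p4mm(self):
        assert nd.drift_to_accuracy(4.0, 10.0) == pytest.approx(0.4)

    def test_zero_drift_zero_error(self):
        assert nd.drift_to_accuracy(0.0, 7.0) == 0.0

    def test_typical_subject_drop(self):
        assert nd.drift_to_accuracy(2.5, 7.2) == pytest.approx(0.18)

    def test_linear_in_each_argument(self):
        assert nd.drift_to_accuracy(8.0, 10.0) == pytest.approx(
            2 * nd.drift_to_accuracy(4.0, 10.0))
        assert nd.drift_to_accuracy(4.0, 20.0) == pytest.approx(
            2 * nd.drift_to_accuracy(4.0, 10.0))
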