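"""Calibration, rates, inner-filter correction, MM and tight-binding fits."""

import numpy as np
import pytest

from fretscreen.kinetics import (
    CalibrationCurve,
    CalibrationError,
    ProgressCurve,
    TitrationSeries,
    bead_delta_fi,
    convert_rate,
    detection_call,
    fit_calibration,
    fit_michaelis_menten,
    fit_tight_binding,
    initial_rate,
    inner_filter_factors,
    michaelis_menten,
    morrison_activity,
    selectivity_table,
)
from fretscreen.simulate import KineticsSimConfig, simulate_progress, simulate_titration

# Published kinetic constants used as generating truths (current substrate
# and library parent) — inputs to simulations, not asserted as outputs.
CURRENT_KCAT, CURRENT_KM = 3.61, 125.2
PARENT_KCAT, PARENT_KM = 1.87, 29.5
DILUTION_SERIES = np.array([200.0 / 2**i for i in range(8)])


class TestCalibration:
    def test_exact_line(self):
        c = np.array([0.1, 0.5, 1, 5, 10, 20.0])
        cal = fit_calibration(c, 50.0 * c)
        assert cal.gradient == pytest.approx(50.0)
        assert cal.r_squared == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1, 2, 3, 4], [7.0, 7.0, 7.0, 7.0])

    def test_noisy_gradient_recovered_within_2pct(self):
        rng = np.random.default_rng(19)
        c = np.linspace(0.1, 20, 12)
        y = 50.0 * c * (1 + rng.normal(0, 0.01, len(c)))
        cal = fit_calibration(c, y)
        assert cal.gradient == pytest.approx(50.0, rel=0.02)

    def test_rfu_conversion_inverts_line(self):
        cal = CalibrationCurve(50.0, 5.0, 1.0)
        assert cal.rfu_to_uM(105.0) == pytest.approx(2.0)


class TestInitialRate:
    def test_exact_linear_trace_uses_whole_window(self):
        t = np.arange(0, 600, 20.0)
        fit = initial_rate(ProgressCurve(t, 3.5 * t + 7))
        assert fit.slope == pytest.approx(3.5)
        assert fit.window == (0, len(t))
        assert not fit.quality_warning

    def test_flat_trace_slope_zero(self):
        t = np.arange(0, 200, 20.0)
        fit = initial_rate(ProgressCurve(t, np.zeros(len(t))))
        assert fit.slope == 0.0

    def test_depletion_trace_slope_near_v0(self):
        # ~10% total conversion of S0 ≈ Km: slope within 3% of Vmax·S0/(Km+S0)
        cfg = KineticsSimConfig(
            kcat_s=PARENT_KCAT, km_uM=PARENT_KM, enzyme_uM=0.03,
            substrate_uM=(30.0,), gradient_rfu_per_uM=50.0,
            read_interval_s=2.0, horizon_s=100.0,
        )
        curve = simulate_progress(cfg)[0]
        v0 = PARENT_KCAT * 0.03 * 30.0 / (PARENT_KM + 30.0) * 50.0  # RFU/s
        conversion = curve.rfu[-1] / (50.0 * 30.0)
        assert 0.05 < conversion < 0.15
        fit = initial_rate(curve)
        assert fit.slope == pytest.approx(v0, rel=0.03)

    def test_nonlinear_trace_falls_back_with_warning(self):
        t = np.arange(0, 200, 20.0)
        with pytest.warns(UserWarning):
            fit = initial_rate(ProgressCurve(t, np.sqrt(t) + np.sin(t) * 5))
        assert fit.quality_warning


class TestConvertRate:
    def test_worked_arithmetic(self):
        cal = CalibrationCurve(gradient=50.0, intercept=0.0, r_squared=1.0)
        # gradient 50 RFU/nM, enzyme 20 nM, rate 100 RFU/s → 0.1 nM/s/nM
        assert convert_rate(100.0, cal, 20.0) == pytest.approx(0.1)

    def test_linearity_and_inverse_linearity(self):
        cal = CalibrationCurve(40.0, 0.0, 1.0)
        base = convert_rate(10.0, cal, 5.0)
        assert convert_rate(20.0, cal, 5.0) == pytest.approx(2 * base)
        assert convert_rate(10.0, cal, 10.0) == pytest.approx(base / 2)
        cal2 = CalibrationCurve(80.0, 0.0, 1.0)
        assert convert_rate(10.0, cal2, 5.0) == pytest.approx(base / 2)

    def test_zero_divisors_rejected(self):
        cal = CalibrationCurve(40.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            convert_rate(1.0, cal, 0.0)


class TestInnerFilter:
    def test_no_quench_gives_unit_factors(self):
        s = [0, 10, 50, 100.0]
        t = inner_filter_factors(s, [500.0] * 4, [100.0] * 4)
        np.testing.assert_allclose(t.factor, 1.0)

    def test_factor_half_doubles_corrected_rate(self):
        t = inner_filter_factors([0.0, 50.0], [500.0, 300.0], [100.0, 100.0])
        assert t.factor_at(50.0) == pytest.approx(0.5)
        corrected = t.correct_rates(np.array([50.0]), np.array([2.0]))
        assert corrected[0] == pytest.approx(4.0)

    def test_exponential_quench_recovered(self):
        alpha = 0.01
        s = np.array([0, 10, 25, 50, 100, 200.0])
        rng = np.random.default_rng(31)
        true = np.exp(-alpha * s)
        with_spike = 100.0 + 400.0 * true * (1 + rng.normal(0, 0.002, len(s)))
        without = np.full(len(s), 100.0)
        t = inner_filter_factors(s, with_spike, without)
        np.testing.assert_allclose(t.factor, true, rtol=0.02)

    def test_factors_bounded_and_anchor_at_one(self):
        t = inner_filter_factors([0.0, 20, 100.0], [500.0, 450.0, 300.0], [100.0] * 3)
        assert t.factor_at(0.0) == 1.0
        assert np.all((t.factor > 0) & (t.factor <= 1.0))

    def test_correction_never_decreases_rates(self):
        t = inner_filter_factors([0.0, 20, 100.0], [500.0, 450.0, 300.0], [100.0] * 3)
        s = np.array([0.0, 20.0, 100.0])
        raw = np.array([1.0, 2.0, 3.0])
        assert np.all(t.correct_rates(s, raw) >= raw)

    def test_missing_zero_point_rejected(self):
        with pytest.raises(ValueError):
            inner_filter_factors([10.0, 50.0], [400.0, 300.0], [100.0, 100.0])


class TestMichaelisMenten:
    def test_half_maximal_rate_at_km(self):
        assert michaelis_menten(CURRENT_KM, 2.0, CURRENT_KM) == pytest.approx(1.0)

    def test_noise_free_recovery_to_1e6_relative(self):
        E = 0.03
        v = CURRENT_KCAT * E * DILUTION_SERIES / (CURRENT_KM + DILUTION_SERIES)
        fit = fit_michaelis_menten(DILUTION_SERIES, v, E)
        assert fit.km_uM == pytest.approx(CURRENT_KM, rel=1e-6)
        assert fit.kcat_s == pytest.approx(CURRENT_KCAT, rel=1e-6)

    def test_efficiency_invariant(self):
        E = 0.03
        v = CURRENT_KCAT * E * DILUTION_SERIES / (CURRENT_KM + DILUTION_SERIES)
        fit = fit_michaelis_menten(DILUTION_SERIES, v, E)
        assert fit.kcat_over_km_M_s == pytest.approx(fit.kcat_s / (fit.km_uM * 1e-6), rel=1e-12)

    def test_noisy_replicates_median_km_within_10pct(self):
        E = 0.03
        truth = PARENT_KCAT * E * DILUTION_SERIES / (PARENT_KM + DILUTION_SERIES)
        rng = np.random.default_rng(47)
        kms = []
        for _ in range(100):
            v = truth * (1 + rng.normal(0, 0.05, len(truth)))
            kms.append(fit_michaelis_menten(DILUTION_SERIES, np.abs(v), E).km_uM)
        assert np.median(kms) == pytest.approx(PARENT_KM, rel=0.10)

    def test_correction_applied_flag_and_effect(self):
        E = 0.03
        v = CURRENT_KCAT * E * DILUTION_SERIES / (CURRENT_KM + DILUTION_SERIES)
        table = inner_filter_factors(
            np.concatenate([[0.0], DILUTION_SERIES]),
            np.concatenate([[500.0], 400.0 * np.exp(-0.005 * DILUTION_SERIES) + 100.0]),
            np.full(9, 100.0),
        )
        fit = fit_michaelis_menten(DILUTION_SERIES, v, E, correction=table)
        assert fit.correction_applied
        assert fit.vmax_uM_s > CURRENT_KCAT * E  # quench undone → larger Vmax


class TestTightBinding:
    INHIBITOR = [1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0]

    def test_zero_inhibitor_full_activity(self):
        assert morrison_activity(0.0, 27.0, 0.1) == pytest.approx(100.0)

    def test_stoichiometric_limit(self):
        # Ki → 0, I = E → activity → 0
        assert morrison_activity(27.0, 27.0, 1e-9) == pytest.approx(0.0, abs=1e-2)

    def test_titration_x_intercept_near_active_concentration(self):
        series = simulate_titration(27.0, 0.1, self.INHIBITOR)
        fit = fit_tight_binding(series, 27.0)
        assert fit.enzyme_active_nM == pytest.approx(27.0, abs=1.0)

    def test_morrison_fit_recovers_generating_parameters(self):
        series = simulate_titration(27.0, 0.5, self.INHIBITOR)
        fit = fit_tight_binding(series, 20.0)
        assert fit.enzyme_fit_nM == pytest.approx(27.0, rel=1e-4)
        assert fit.ki_app_nM == pytest.approx(0.5, rel=1e-3)

    def test_no_inhibition_rejected(self):
        series = TitrationSeries(np.array(self.INHIBITOR), np.full(8, 99.0))
        with pytest.raises(ValueError):
            fit_tight_binding(series, 27.0)


class TestSelectivityAndDetection:
    def test_table3_efficiency_folds(self):
        table = selectivity_table(
            {"parent": 6.32e4, "hit26": 4.44e4, "current": 2.91e4}, reference="parent"
        )
        # the same arithmetic read the other way: parent and hit-26 efficiency
        # relative to the current substrate
        assert 6.32e4 / 2.91e4 == pytest.approx(2.2, abs=0.05)
        assert 4.44e4 / 2.91e4 == pytest.approx(1.5, abs=0.05)
        assert table["current"]["fold"] == pytest.approx(6.32 / 2.91, rel=1e-9)

    def test_identical_rates_fold_one(self):
        t = selectivity_table({"a": 3.0, "b": 3.0}, reference="a")
        assert t["b"]["fold"] == 1.0

    def test_simple_fold(self):
        t = selectivity_table({"a": 10.0, "b": 2.0}, reference="a")
        assert t["b"]["fold"] == 5.0
        assert t["b"]["percent_of_reference"] == pytest.approx(20.0)

    def test_zero_rate_reported_as_bound(self):
        t = selectivity_table({"a": 10.0, "b": 0.0}, reference="a")
        assert t["b"]["fold"] == np.inf and "fold" in t["b"]["note"]

    def test_detection_crossing_interpolated(self):
        t = np.array([0.0, 100.0, 200.0])
        rfu = np.array([0.0, 200.0, 600.0])
        detected, t_cross = detection_call(t, rfu, threshold=300.0, horizon_s=500.0)
        assert detected and t_cross == pytest.approx(125.0)

    def test_flat_trace_not_detected(self):
        detected, t_cross = detection_call([0, 100, 200.0], [5.0, 5.0, 5.0], 300.0, 500.0)
        assert not detected and t_cross is None

    def test_horizon_excludes_late_crossing(self):
        detected, _ = detection_call([0, 100, 200.0], [0.0, 10.0, 600.0], 300.0, 150.0)
        assert not detected


class TestBeadDeltaFI:
    def test_constant_series_zero(self):
        np.testing.assert_allclose(bead_delta_fi([5, 5, 5.0], [2, 2, 2.0]), 0.0)

    def test_rise_with_flat_background(self):
        # a bead whose net fluorescence rises by 2010 over the experiment
        fi = [100.0, 900.0, 2110.0]
        bg = [50.0, 50.0, 50.0]
        assert bead_delta_fi(fi, bg)[-1] == pytest.approx(2010.0)

    def test_common_drift_cancels(self):
        fi = [100.0, 200.0, 300.0]
        bg = [50.0, 150.0, 250.0]
        np.testing.assert_allclose(bead_delta_fi(fi, bg), 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bead_delta_fi([1.0, 2.0], [1.0])
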