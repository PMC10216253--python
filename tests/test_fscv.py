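"""Dopamine release/uptake traces: exact kinetics, fitting, curves, calibration."""

import numpy as np
import pandas as pd
import pytest

from nicodose.fscv import (
    CollinearityError,
    FSCVTrace,
    MMParams,
    NoSignalError,
    ReferenceError_,
    ResolutionError,
    StimPattern,
    apply_calibration,
    calibrate_electrode,
    fit_mm,
    frequency_response,
    intensity_curve,
    mm_decay,
    nicotine_modulation_curve,
    peak_da,
    simulate_trace,
)

P = MMParams(vmax=1.5, da_per_pulse=1.0, km=0.16)


def euler_oracle(params: MMParams, stim: StimPattern, duration: float,
                 dt: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force explicit-Euler integration of release-plus-uptake."""
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    c = np.zeros(n + 1)
    cur, j = 0.0, 0
    pulses = stim.pulse_times
    for i in range(n + 1):
        while j < pulses.size and pulses[j] <= t[i] + 1e-12:
            cur += params.da_per_pulse
            j += 1
        c[i] = cur
        cur = max(cur - dt * params.vmax * cur / (params.km + cur), 0.0)
    return t, c


class TestSimulation:
    def test_no_uptake_single_pulse_peak_is_release_increment(self):
        p = MMParams(vmax=1e-9, da_per_pulse=1.0, km=0.16)
        tr = simulate_trace(p, StimPattern.single_pulse(t0=0.5), 3.0, 0.01)
        peak, t_peak = peak_da(tr)
        assert peak == pytest.approx(1.0, abs=1e-6)
        assert tr.da_conc[-1] == pytest.approx(1.0, abs=1e-6)
        assert t_peak == pytest.approx(0.5)

    def test_linearized_decay_rate_when_da_much_below_km(self):
        # [DA] << Km: uptake is first order with rate vmax/km
        p = MMParams(vmax=0.5, da_per_pulse=0.001, km=0.16)
        tr = simulate_trace(p, StimPattern.single_pulse(t0=0.0), 1.0, 0.01)
        logc = np.log(tr.da_conc[tr.da_conc > 0])
        slope = np.polyfit(tr.time[: logc.size], logc, 1)[0]
        assert -slope == pytest.approx(p.vmax / p.km, rel=0.01)

    def test_fast_train_sums_pulses_when_uptake_negligible(self):
        p = MMParams(vmax=1e-9, da_per_pulse=1.0, km=0.16)
        tr = simulate_trace(p, StimPattern.train(4, 100.0), 2.0, 0.005)
        assert peak_da(tr)[0] == pytest.approx(4.0, rel=1e-6)

    def test_matches_explicit_euler_oracle(self):
        stim = StimPattern.train(4, 30.0, t0=0.5)
        tr = simulate_trace(P, stim, 5.0, 0.01)
        t_f, c_f = euler_oracle(P, stim, 5.0)
        diff = np.abs(np.interp(tr.time, t_f, c_f) - tr.da_conc)
        assert diff.max() < 1e-3

    def test_coarse_dt_rejected_for_train(self):
        with pytest.raises(ResolutionError):
            simulate_trace(P, StimPattern.train(4, 100.0), 1.0, 0.1)

    def test_trace_non_negative_and_vmax_monotonicity(self):
        stim = StimPattern.single_pulse(t0=0.2)
        lo = simulate_trace(MMParams(0.5, 1.0, 0.16), stim, 3.0, 0.01)
        hi = simulate_trace(MMParams(2.5, 1.0, 0.16), stim, 3.0, 0.01)
        assert np.all(lo.da_conc >= 0) and np.all(hi.da_conc >= 0)
        after = lo.time > 0.2
        assert np.all(hi.da_conc[after] <= lo.da_conc[after] + 1e-12)

    def test_mm_decay_closed_form_identity(self):
        # the implicit relation Km·ln(c0/c) + (c0−c) = Vmax·t holds exactly
        c0, vmax, km = 2.0, 1.5, 0.16
        for t in (0.1, 0.5, 1.0):
            c = mm_decay(c0, t, vmax, km)
            assert km * np.log(c0 / c) + (c0 - c) == pytest.approx(vmax * t, rel=1e-9)


class TestFitting:
    def test_noiseless_round_trip_identity(self):
        tr = simulate_trace(P, StimPattern.single_pulse(t0=0.5), 3.0, 0.01)
        est, diag = fit_mm(tr, km_fixed=P.km)
        assert est.vmax == pytest.approx(P.vmax, rel=1e-3)
        assert est.da_per_pulse == pytest.approx(P.da_per_pulse, rel=1e-3)
        assert diag["residual_rms"] < 1e-8

    def test_train_round_trip_identity(self):
        stim = StimPattern.train(4, 30.0, t0=0.5)
        tr = simulate_trace(P, stim, 3.0, 0.01)
        est, _ = fit_mm(tr, km_fixed=P.km)
        assert est.vmax == pytest.approx(P.vmax, rel=1e-3)
        assert est.da_per_pulse == pytest.approx(P.da_per_pulse, rel=1e-3)

    def test_flat_trace_raises_no_signal(self):
        t = np.arange(0, 3, 0.01)
        tr = FSCVTrace(t, np.zeros_like(t), stim=StimPattern.single_pulse())
        with pytest.raises(NoSignalError):
            fit_mm(tr)

    def test_noisy_recovery_within_five_percent_median(self):
        rng = np.random.default_rng(42)
        stim = StimPattern.single_pulse(t0=0.5)
        clean = simulate_trace(P, stim, 3.0, 0.02)
        errs_v, errs_d = [], []
        for _ in range(20):
            noisy = FSCVTrace(
                clean.time,
                np.maximum(clean.da_conc + rng.normal(0, 0.02, clean.time.size), 0),
                stim=stim,
            )
            est, _ = fit_mm(noisy, km_fixed=P.km)
            errs_v.append(abs(est.vmax / P.vmax - 1))
            errs_d.append(abs(est.da_per_pulse / P.da_per_pulse - 1))
        assert np.median(errs_v) < 0.05 and np.median(errs_d) < 0.05


class TestCurves:
    def test_identical_traces_give_flat_normalized_intensity_curve(self):
        tr = simulate_trace(P, StimPattern.single_pulse(), 2.0, 0.05)
        curve = intensity_curve({v: tr for v in (1.0, 2.0, 3.0)})
        np.testing.assert_allclose(curve.normalized, 1.0)
        assert curve.normalized.max() == 1.0

    def test_duplicate_intensities_rejected(self):
        tr = simulate_trace(P, StimPattern.single_pulse(), 2.0, 0.05)
        with pytest.raises(ValueError):
            intensity_curve([(1.0, tr), (1.0, tr)])

    def test_frequency_train_identical_to_reference_reads_100_percent(self):
        tr = simulate_trace(P, StimPattern.single_pulse(), 2.0, 0.05)
        curve = frequency_response(tr, {30.0: tr})
        assert curve.percent_of_single_pulse[0] == pytest.approx(100.0)

    def test_negligible_uptake_100hz_train_reads_400_percent(self):
        p = MMParams(vmax=1e-9, da_per_pulse=1.0, km=0.16)
        single = simulate_trace(p, StimPattern.single_pulse(), 2.0, 0.005)
        train = simulate_trace(p, StimPattern.train(4, 100.0), 2.0, 0.005)
        curve = frequency_response(single, {100.0: train})
        assert curve.percent_of_single_pulse[0] == pytest.approx(400.0, rel=1e-6)

    def test_trains_always_exceed_single_pulse_with_residual_da(self):
        single = simulate_trace(P, StimPattern.single_pulse(), 3.0, 0.005)
        trains = {
            f: simulate_trace(P, StimPattern.train(4, f), 3.0, 0.005)
            for f in (3.0, 10.0, 30.0, 100.0)
        }
        curve = frequency_response(single, trains)
        assert np.all(curve.percent_of_single_pulse >= 100.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ReferenceError_):
            frequency_response(None, {})


class TestCalibration:
    def test_exact_line_recovered_with_zero_residual(self):
        bg = np.array([50.0, 80.0, 110.0, 140.0, 170.0])
        sens = 2.0 + 0.05 * bg
        model = calibrate_electrode(
            pd.DataFrame({"background_na": bg, "sensitivity_na_per_um": sens})
        )
        np.testing.assert_allclose(model.coefficients, [2.0, 0.05], atol=1e-10)
        pred = model.predict_sensitivity({"background_na": 100.0})
        assert pred[0] == pytest.approx(7.0)

    def test_noisy_coefficients_within_standard_errors(self):
        rng = np.random.default_rng(3)
        bg = np.linspace(40, 200, 30)
        sens = 1.5 + 0.04 * bg + rng.normal(0, 0.2, bg.size)
        model = calibrate_electrode(
            pd.DataFrame({"background_na": bg, "sensitivity_na_per_um": sens})
        )
        assert abs(model.coefficients[1] - 0.04) < 3 * model.stderr[1]

    def test_collinear_features_rejected(self):
        df = pd.DataFrame({
            "f1": [1.0, 2.0, 3.0, 4.0, 5.0],
            "f2": [2.0, 4.0, 6.0, 8.0, 10.0],
            "sensitivity_na_per_um": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        with pytest.raises(CollinearityError):
            calibrate_electrode(df)

    def test_apply_calibration_converts_current_to_concentration(self):
        bg = np.array([50.0, 100.0, 150.0, 200.0])
        model = calibrate_electrode(
            pd.DataFrame({"background_na": bg,
                          "sensitivity_na_per_um": 0.1 * bg})
        )
        t = np.arange(0, 1, 0.1)
        current = np.full_like(t, 50.0)  # nA
        tr = apply_calibration(t, current, model, {"background_na": 100.0})
        np.testing.assert_allclose(tr.da_conc, 5.0)  # 50 nA / (10 nA/μM)


class TestModulation:
    doses = np.array([1e-9, 3.16e-9, 1e-8, 3.16e-8, 1e-7])

    def test_flat_curve_flagged_not_fitted(self):
        out = nicotine_modulation_curve(2.0, self.doses, np.full(5, 2.0))
        assert out.flat and out.fit is None

    def test_baseline_normalization_and_ic50_recovery(self):
        from nicodose.hill import hill_response
        rel = 2.0 * hill_response(self.doses, 1e-8, 1.2, 1.0, direction="inhibition")
        out = nicotine_modulation_curve(2.0, self.doses, rel)
        assert not out.flat
        assert out.fit.ec50 == pytest.approx(1e-8, rel=1e-3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            nicotine_modulation_curve(0.0, self.doses, np.ones(5))

    def test_group_ic50_ordering_recovered(self):
        # slices generated with a higher true IC50 in the resistant group keep
        # their ordering after per-slice fitting
        from nicodose.hill import hill_response
        rng = np.random.default_rng(5)
        def group_mean(ic50_true, n_slices=6):
            vals = []
            for _ in range(n_slices):
                base = rng.uniform(1.0, 3.0)
                rel = base * np.maximum(
                    hill_response(self.doses, ic50_true, 1.0, 1.0,
                                  direction="inhibition")
                    + rng.normal(0, 0.02, 5), 1e-3,
                )
                vals.append(nicotine_modulation_curve(base, self.doses, rel).fit.ec50)
            return np.mean(vals)
        assert group_mean(2.5e-8) > group_mean(0.8e-8)
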