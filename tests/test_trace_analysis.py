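"""Signal conditioning, saccade detection, exclusions and per-trial metrics."""

import math

import numpy as np
import pytest

from catchup_saccades import (
    AnalysisConfig,
    EyeTrace,
    analyze_trial,
    apply_exclusions,
    build_trial,
    classify_trial,
    compute_errors,
    compute_pe_pred,
    compute_txe,
    compute_txt,
    detect_saccades,
    differentiate_central,
    lowpass_zero_phase,
    pe_pred_at_step,
    sample_presaccadic,
)
from catchup_saccades.synthesis import inject_blink, inject_saccade, synthesize_pursuit
from catchup_saccades.trace_analysis import SaccadeEvent


def _analyze_arrays(trace):
    fs = trace.sample_rate
    eye_f = lowpass_zero_phase(trace.eye_x, fs=fs)
    vel = differentiate_central(eye_f, fs)
    acc = differentiate_central(vel, fs)
    return eye_f, vel, acc


class TestFiltering:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        assert np.allclose(lowpass_zero_phase(x), x)

    def test_passband_and_stopband(self):
        t = np.arange(2000) / 1000.0
        passband = np.sin(2 * np.pi * 10 * t)
        y = lowpass_zero_phase(passband)
        mid = slice(500, 1500)
        assert np.max(np.abs(y[mid])) > 0.95  # < 5% attenuation at 10 Hz
        stopband = np.sin(2 * np.pi * 100 * t)
        y = lowpass_zero_phase(stopband)
        assert np.max(np.abs(y[mid])) < 0.10  # > 90% attenuation at 100 Hz

    def test_zero_phase_peak_unshifted(self):
        x = np.exp(-0.5 * ((np.arange(1000) - 500) / 30.0) ** 2)
        y = lowpass_zero_phase(x)
        assert np.argmax(y) == 500

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(np.zeros(5))

    def test_nan_gaps_survive_filtering(self):
        x = np.sin(np.arange(1000) / 50.0)
        x[300:350] = np.nan
        y = lowpass_zero_phase(x)
        assert np.isnan(y[300:350]).all()
        assert np.isfinite(y[:300]).all() and np.isfinite(y[350:]).all()


class TestDifferentiation:
    def test_exact_on_linear_ramp(self):
        x = np.arange(100, dtype=float)  # 1 deg/ms at 1000 Hz
        v = differentiate_central(x, 1000.0)
        assert np.allclose(v, 1000.0)

    def test_acceleration_exact_on_quadratic(self):
        t = np.arange(200) / 1000.0
        x = 3.0 * t**2
        acc = differentiate_central(differentiate_central(x, 1000.0), 1000.0)
        assert np.allclose(acc[2:-2], 6.0, atol=1e-6)

    def test_nan_propagates_through_stencil(self):
        x = np.arange(20, dtype=float)
        x[10] = np.nan
        v = differentiate_central(x, 1000.0)
        assert np.isnan(v[9]) and np.isnan(v[11])
        assert np.isfinite(v[8]) and np.isfinite(v[12])


class TestDetection:
    def test_pure_pursuit_has_no_events(self, simple_traj, rng):
        trace = synthesize_pursuit(simple_traj, motor_sd=1.0, rng=rng)
        events = detect_saccades(trace.time, *_analyze_arrays(trace))
        assert events == []

    @pytest.mark.parametrize("amplitude", [2.0, 5.0, -8.0])
    def test_injected_saccade_recovered(self, simple_traj, rng, amplitude):
        trace = synthesize_pursuit(simple_traj, motor_sd=0.0)
        onset = trace.step2_time + 200.0
        inject_saccade(trace, onset=onset, amplitude=amplitude)
        eye_f, vel, acc = _analyze_arrays(trace)
        events = detect_saccades(trace.time, eye_f, vel, acc)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset == pytest.approx(onset, abs=5.0)
        # measured displacement includes the pursuit carried under the saccade
        carried = vel[int(ev.onset) - 10] * ev.duration / 1000.0  # baseline pursuit
        assert ev.amplitude == pytest.approx(amplitude + carried, abs=0.5)

    def test_two_close_saccades_not_merged(self, simple_traj):
        trace = synthesize_pursuit(simple_traj, motor_sd=0.0)
        on1 = trace.step2_time + 150.0
        dur1 = 2.2 * 4.0 + 21.0
        on2 = on1 + dur1 + 50.0
        inject_saccade(trace, onset=on1, amplitude=4.0)
        inject_saccade(trace, onset=on2, amplitude=4.0)
        events = detect_saccades(trace.time, *_analyze_arrays(trace))
        assert len(events) == 2

    def test_detection_is_translation_equivariant(self, simple_traj):
        trace = synthesize_pursuit(simple_traj, motor_sd=0.0)
        inject_saccade(trace, onset=trace.step2_time + 200.0, amplitude=5.0)
        eye_f, vel, acc = _analyze_arrays(trace)
        base = detect_saccades(trace.time, eye_f, vel, acc)
        k = 37
        shifted = detect_saccades(
            trace.time, np.roll(eye_f, k), np.roll(vel, k), np.roll(acc, k)
        )
        assert len(shifted) == len(base)
        assert shifted[0].onset - base[0].onset == pytest.approx(k, abs=1e-9)


class TestCrossingTimes:
    @pytest.mark.parametrize(
        "ps, vs, expected",
        [(5.0, 10.0, -500.0), (5.0, -10.0, 500.0), (-6.0, 12.0, 500.0)],
    )
    def test_txt_worked_examples(self, ps, vs, expected):
        assert compute_txt(ps, vs) == pytest.approx(expected)

    def test_txt_undefined_for_zero_velocity_step(self):
        assert math.isnan(compute_txt(5.0, 0.0))

    @pytest.mark.parametrize(
        "pe, rs, expected", [(-1.0, 10.0, 100.0), (2.0, -4.0, 500.0)]
    )
    def test_txe_formula(self, pe, rs, expected):
        assert compute_txe(pe, rs) == pytest.approx(expected)

    def test_txe_undefined_marker_near_zero_slip(self):
        assert math.isnan(compute_txe(1.0, 0.0))
        assert math.isnan(compute_txe(1.0, 1e-9))

    @pytest.mark.parametrize(
        "pe, rs, expected", [(5.0, 10.0, 6.5), (5.0, -10.0, 3.5), (0.0, 0.0, 0.0)]
    )
    def test_pe_pred_worked_examples(self, pe, rs, expected):
        assert compute_pe_pred(pe, rs, 0.15) == pytest.approx(expected)

    def test_pe_pred_zero_iff_txe_equals_dt(self):
        # PE + dt*RS = 0 exactly when -PE/RS = dt (noiseless identity)
        for pe in (-6.0, -1.0, 2.0, 8.0):
            rs = -pe / 0.15
            assert compute_pe_pred(pe, rs, 0.15) == pytest.approx(0.0, abs=1e-12)
            assert compute_txe(pe, rs) == pytest.approx(150.0)


class TestErrorsAndSampling:
    def test_perfect_tracking_zero_errors(self, simple_traj):
        trace = EyeTrace(
            time=simple_traj.t.copy(), target_x=simple_traj.x.copy(),
            eye_x=simple_traj.x.copy(), step2_time=simple_traj.event_times["step2"],
            spec=simple_traj.spec,
        )
        pe, rs = compute_errors(trace)
        mid = slice(300, 700)  # away from steps and edges
        assert np.allclose(pe[mid], 0.0, atol=0.02)
        assert np.allclose(rs[mid], 0.0, atol=1.0)

    def test_lagged_ramp_steady_state_error(self):
        # eye lags a 10 deg/s ramp by 100 ms -> PE ~ 1 deg
        t = np.arange(1500, dtype=float)
        target = 10.0 * t / 1000.0
        eye = 10.0 * np.clip(t - 100.0, 0, None) / 1000.0
        trace = EyeTrace(time=t, target_x=target, eye_x=eye, step2_time=0.0)
        pe, _ = compute_errors(trace)
        assert np.median(pe[800:1400]) == pytest.approx(1.0, abs=0.05)
        assert np.all(pe[800:1400] > 0)  # target right of eye -> positive PE

    def test_pe_pred_at_step_window_average(self):
        time = np.arange(200, dtype=float)
        const = np.full(200, 6.5)
        assert pe_pred_at_step(const, time, 100.0, 50.0) == pytest.approx(6.5)
        linear = np.where(time >= 100.0, (time - 100.0) / 49.0, 0.0)
        # mean of a 0..1 linear ramp over the window
        assert pe_pred_at_step(linear, time, 100.0, 50.0) == pytest.approx(0.5, abs=0.02)

    def test_presaccadic_sample_matches_analytic_trace(self):
        time = np.arange(1000, dtype=float)
        pe = 0.01 * time  # known linear PE
        rs = np.full(1000, 10.0)
        pe_s, rs_s, pp, txe, clipped = sample_presaccadic(
            pe, rs, time, onset=500.0, step2=200.0
        )
        assert pe_s == pytest.approx(4.0)  # sampled at onset - 100 ms
        assert pp == pytest.approx(4.0 + 1.5)
        assert not clipped
        # lead reaching past the step clips to the step and flags
        *_, clipped = sample_presaccadic(pe, rs, time, onset=250.0, step2=200.0)
        assert clipped

    def test_smooth_trial_uses_window_average(self):
        time = np.arange(1000, dtype=float)
        pe = np.where(time >= 200.0, 2.0, 0.0)
        rs = np.zeros(1000)
        pe_s, _, _, _, _ = sample_presaccadic(pe, rs, time, onset=None, step2=200.0)
        assert pe_s == pytest.approx(2.0)


class TestExclusionsAndClassification:
    def _trace_with_events(self, simple_traj, onsets_amps):
        trace = synthesize_pursuit(simple_traj, motor_sd=0.0)
        for onset, amp in onsets_amps:
            inject_saccade(trace, onset=trace.step2_time + onset, amplitude=amp)
        events = detect_saccades(trace.time, *_analyze_arrays(trace))
        pe, _ = compute_errors(trace)
        return trace, events, pe

    def test_clean_trial_kept(self, simple_traj):
        trace, events, pe = self._trace_with_events(simple_traj, [(200.0, 5.0)])
        keep, reason = apply_exclusions(trace, events, pe)
        assert keep and reason == "ok"

    def test_blink_at_step_excluded(self, simple_traj):
        trace, events, pe = self._trace_with_events(simple_traj, [])
        inject_blink(trace, trace.step2_time - 20.0, 150.0)
        keep, reason = apply_exclusions(trace, events, pe)
        assert not keep and reason == "blink"

    def test_saccade_in_flight_at_step_excluded(self, simple_traj):
        trace, events, pe = self._trace_with_events(simple_traj, [(-15.0, 5.0)])
        keep, reason = apply_exclusions(trace, events, pe)
        assert not keep and reason == "saccade_at_step"

    def test_double_saccade_excluded(self, simple_traj):
        dur = 2.2 * 4.0 + 21.0
        trace, events, pe = self._trace_with_events(
            simple_traj, [(150.0, 4.0), (150.0 + dur + 40.0, 4.0)]
        )
        keep, reason = apply_exclusions(trace, events, pe)
        assert not keep and reason == "double_saccade"

    def test_wrong_direction_saccade_excluded(self, simple_traj):
        # simple_spec's post-step2 error is positive; a leftward saccade is
        # directed at the first ramp's trajectory
        trace, events, pe = self._trace_with_events(simple_traj, [(250.0, -5.0)])
        keep, reason = apply_exclusions(trace, events, pe)
        assert not keep and reason == "wrong_direction"

    @pytest.mark.parametrize(
        "trigger, expected",
        [(120.0, "early"), (174.9, "early"), (175.0, "late"), (300.0, "late"),
         (450.0, "smooth"), (None, "smooth")],
    )
    def test_classification_rule(self, trigger, expected):
        assert classify_trial(trigger) == expected


class TestAnalyzeTrial:
    def test_metrics_row_on_scripted_trace(self, simple_traj):
        trace = synthesize_pursuit(simple_traj, motor_sd=0.0)
        inject_saccade(trace, onset=trace.step2_time + 250.0, amplitude=6.0)
        row = analyze_trial(trace)
        assert not row["excluded"]
        assert row["klass"] == "late"
        assert row["trigger_time"] == pytest.approx(250.0, abs=5.0)
        assert row["txt"] == pytest.approx(simple_traj.spec.txt_ms)
        assert row["n_saccades_post"] == 1

    def test_determinism_of_metrics(self, simple_traj, rng):
        trace = synthesize_pursuit(simple_traj, motor_sd=1.0, rng=rng)
        inject_saccade(trace, onset=trace.step2_time + 220.0, amplitude=5.0)
        a, b = analyze_trial(trace), analyze_trial(trace)
        assert a == b

    def test_phase_plot_sign_law(self, rng):
        # PE and RS same sign -> |PE| increasing; opposite -> decreasing
        from catchup_saccades.task_design import draw_trial_spec

        checked = 0
        while checked < 8:
            spec = draw_trial_spec(rng, blur=False)
            traj = build_trial(spec)
            trace = EyeTrace(
                time=traj.t.copy(), target_x=traj.x.copy(),
                eye_x=np.full_like(traj.x, traj.x[0]),  # stationary eye
                step2_time=traj.event_times["step2"], spec=spec,
            )
            pe, rs = compute_errors(trace)
            i = int(traj.event_times["step2"]) + 300
            if i + 12 >= pe.size or abs(rs[i]) < 1.0 or abs(pe[i]) < 0.3:
                continue
            d_abs = abs(pe[i + 10]) - abs(pe[i])
            assert (d_abs > 0) == (np.sign(pe[i]) == np.sign(rs[i]))
            checked += 1
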