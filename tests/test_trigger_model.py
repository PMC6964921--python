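"""Unit and property tests of the stochastic trigger model components."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catchup_saccades import (
    DecisionState,
    ModelParams,
    NoiseModel,
    PredictedError,
    SensoryEstimate,
    accumulate_decision,
    confidence_outside_fovea,
    kalman_update,
    observe,
    plan_saccade,
    predict_error,
    simulate_trial,
)
from catchup_saccades.trigger_model import saccade_duration_ms, min_jerk_displacement


class TestObserve:
    def test_zero_noise_returns_truth(self, rng):
        noise = NoiseModel(pos_sd_clear=0.0, pos_sd_blur=0.0, vel_sd_base=0.0,
                           sdn_coef=0.0, pos_sdn_coef=0.0)
        assert observe(3.0, -7.0, noise, blur=False, rng=rng) == (3.0, -7.0)

    def test_monte_carlo_sds_match_closed_form(self, rng):
        noise = NoiseModel()
        pe_true, rs_true = 2.0, 40.0
        draws = np.array(
            [observe(pe_true, rs_true, noise, blur=True, rng=rng) for _ in range(10_000)]
        )
        assert np.std(draws[:, 0]) == pytest.approx(noise.pos_sd(True, rs_true), rel=0.05)
        assert np.std(draws[:, 1]) == pytest.approx(noise.vel_sd(rs_true), rel=0.05)

    def test_signal_dependent_noise_grows_with_slip(self, rng):
        noise = NoiseModel()
        assert noise.vel_sd(40.0) > noise.vel_sd(10.0)
        assert noise.pos_sd(False, 40.0) > noise.pos_sd(False, 0.0)

    def test_blur_never_sharper_than_clear(self):
        with pytest.raises(ValueError):
            NoiseModel(pos_sd_clear=2.0, pos_sd_blur=1.0)


class TestKalmanUpdate:
    def _est(self, pe=0.0, rs=0.0, var=4.0):
        return SensoryEstimate(pe, rs, np.diag([var, var]))

    def test_tiny_observation_noise_pins_posterior_to_observation(self):
        noise = NoiseModel(pos_sd_clear=1e-4, vel_sd_base=1e-4, sdn_coef=0.0,
                           pos_sdn_coef=0.0)
        post = kalman_update(self._est(), (5.0, -10.0), noise, dt_step=0.001)
        assert post.pe_mean == pytest.approx(5.0, abs=1e-2)
        assert post.rs_mean == pytest.approx(-10.0, abs=1e-2)

    def test_huge_observation_noise_keeps_prediction(self):
        noise = NoiseModel(pos_sd_clear=1e6, pos_sd_blur=1e6, vel_sd_base=1e6,
                           sdn_coef=0.0, pos_sdn_coef=0.0)
        prior = self._est(pe=2.0, rs=10.0)
        post = kalman_update(prior, (50.0, -50.0), noise, dt_step=0.001)
        assert post.pe_mean == pytest.approx(2.0 + 0.001 * 10.0, abs=1e-4)
        assert post.rs_mean == pytest.approx(10.0, abs=1e-4)

    def test_covariance_trace_contracts_on_constant_truth(self, rng):
        noise = NoiseModel(sdn_coef=0.0, pos_sdn_coef=0.0)  # fixed observation noise
        est = self._est(var=25.0)
        traces = [np.trace(est.cov)]
        for _ in range(50):
            obs = observe(3.0, 0.0, noise, blur=False, rng=rng)
            est = kalman_update(est, obs, noise, dt_step=0.001)
            traces.append(np.trace(est.cov))
        diffs = np.diff(traces)
        assert np.all(diffs <= 1e-9)

    def test_posterior_covariance_stays_psd(self, rng):
        noise = NoiseModel()
        est = self._est(var=1.0)
        for _ in range(200):
            obs = observe(0.0, 5.0, noise, blur=True, rng=rng)
            est = kalman_update(est, obs, noise, dt_step=0.001)
        assert np.linalg.eigvalsh(est.cov).min() >= 0.0

    def test_standardized_innovations_have_unit_variance(self, rng):
        # filter consistency on data generated from the filter's own model
        noise = NoiseModel(sdn_coef=0.0, pos_sdn_coef=0.0)
        h, q, qp = 0.001, noise.process_sd, noise.pos_process_sd
        pe, rs = 0.0, 0.0
        est = self._est(var=4.0)
        z_innov = []
        for _ in range(8_000):
            rs += q * math.sqrt(h) * rng.standard_normal()
            pe += h * rs + qp * math.sqrt(h) * rng.standard_normal()
            obs = observe(pe, rs, noise, blur=False, rng=rng)
            # innovation of the position channel, standardized by S
            pred_pe = est.pe_mean + h * est.rs_mean
            s = est.cov[0, 0] + 2 * h * est.cov[0, 1] + h * h * est.cov[1, 1] \
                + qp * qp * h + noise.pos_sd_clear ** 2
            z_innov.append((obs[0] - pred_pe) / math.sqrt(s))
            est = kalman_update(est, obs, noise, dt_step=h)
        assert np.var(z_innov[500:]) == pytest.approx(1.0, rel=0.10)


class TestPredictError:
    @pytest.mark.parametrize(
        "pe, rs, dt, expected",
        [(5.0, 10.0, 0.15, 6.5), (5.0, -10.0, 0.15, 3.5), (2.0, 7.0, 0.0, 2.0)],
    )
    def test_mean_extrapolation(self, pe, rs, dt, expected):
        est = SensoryEstimate(pe, rs, np.diag([0.1, 0.2]))
        pred = predict_error(est, dt)
        assert pred.mean == pytest.approx(expected)

    def test_variance_propagation(self):
        cov = np.array([[0.3, 0.05], [0.05, 2.0]])
        est = SensoryEstimate(0.0, 0.0, cov)
        dt = 0.15
        pred = predict_error(est, dt)
        expected = cov[0, 0] + 2 * dt * cov[0, 1] + dt * dt * cov[1, 1]
        assert pred.var == pytest.approx(expected)
        assert predict_error(est, 0.0).var == pytest.approx(cov[0, 0])


class TestConfidence:
    def test_symmetry_at_zero_mean(self):
        p_r, p_l, _ = confidence_outside_fovea(PredictedError(0.0, 1.0, 0.15), 1.0)
        assert p_r == pytest.approx(p_l)

    def test_large_mean_saturates(self):
        p_r, p_l, log_ratio = confidence_outside_fovea(
            PredictedError(50.0, 1.0, 0.15), 1.0
        )
        assert p_r == pytest.approx(1.0, abs=1e-9)
        assert log_ratio > 100.0

    def test_tail_at_own_mean(self):
        # X ~ N(r, 1): P(X > r) = 1/2 exactly
        p_r, _, _ = confidence_outside_fovea(PredictedError(1.0, 1.0, 0.15), 1.0)
        assert p_r == pytest.approx(0.5)

    def test_point_mass_limits(self):
        _, _, lr_out = confidence_outside_fovea(PredictedError(3.0, 0.0, 0.15), 1.0)
        _, _, lr_in = confidence_outside_fovea(PredictedError(0.3, 0.0, 0.15), 1.0)
        assert lr_out == math.inf and lr_in == -math.inf

    @settings(max_examples=100, deadline=None)
    @given(
        mean=st.floats(-30, 30),
        sd=st.floats(0.05, 5),
        r=st.floats(0.2, 3),
    )
    def test_log_ratio_matches_direct_computation_when_stable(self, mean, sd, r):
        from scipy.stats import norm

        p_r, p_l, log_ratio = confidence_outside_fovea(
            PredictedError(mean, sd * sd, 0.15), r
        )
        p_in = norm.cdf(r, mean, sd) - norm.cdf(-r, mean, sd)
        if 1e-12 < p_in < 1 - 1e-12:
            direct = math.log(max(p_r, p_l) / p_in)
            assert log_ratio == pytest.approx(direct, rel=1e-4, abs=1e-6)


class TestAccumulator:
    def test_linear_rise_trigger_time(self):
        state = DecisionState(threshold=2.0)
        c = 10.0  # constant confidence rate, 1/s
        while state.triggered_at is None:
            accumulate_decision(state, c, 0.001)
        assert state.triggered_at == pytest.approx(2.0 / c * 1000.0, abs=1.5)

    def test_nonpositive_evidence_never_triggers(self):
        state = DecisionState(threshold=1.0)
        for _ in range(5_000):
            accumulate_decision(state, -3.0, 0.001)
        assert state.triggered_at is None
        assert state.evidence == 0.0

    def test_larger_predicted_error_triggers_earlier(self):
        def trigger_time(mean):
            state = DecisionState(threshold=2.0)
            pred = PredictedError(mean, 0.25, 0.15)
            _, _, lr = confidence_outside_fovea(pred, 1.0)
            for _ in range(10_000):
                accumulate_decision(state, lr, 0.001)
                if state.triggered_at is not None:
                    return state.triggered_at
            return math.inf

        assert trigger_time(10.0) < trigger_time(4.0) < trigger_time(2.5)


class TestPlanSaccade:
    def test_zero_slip_amplitude_equals_pe(self):
        est = SensoryEstimate(4.0, 0.0, np.diag([0.1, 0.1]))
        sac = plan_saccade(est, ModelParams(), now=500.0)
        assert sac.amplitude == pytest.approx(4.0)
        assert sac.onset == pytest.approx(600.0)

    def test_amplitude_extrapolates_over_landing_horizon(self):
        est = SensoryEstimate(2.0, 10.0, np.diag([0.1, 0.1]))
        params = ModelParams(motor_delay=100.0)
        sac = plan_saccade(est, params, now=0.0)
        dur = saccade_duration_ms(sac.amplitude)
        expected = 2.0 + (100.0 + dur / 2.0) / 1000.0 * 10.0
        assert sac.amplitude == pytest.approx(expected, abs=0.05)

    def test_main_sequence_duration_plausible(self):
        assert 20.0 <= saccade_duration_ms(10.0) <= 100.0
        prof = min_jerk_displacement(5.0, saccade_duration_ms(5.0), 1000.0)
        assert prof[-1] == pytest.approx(5.0, abs=1e-9)
        assert np.all(np.diff(prof) >= -1e-12)  # monotone displacement


class TestSimulateTrial:
    def test_zero_noise_infinite_threshold_pure_pursuit(self, simple_traj, rng):
        params = ModelParams(
            threshold=math.inf,
            noise=NoiseModel(pos_sd_clear=0.0, pos_sd_blur=0.0, vel_sd_base=0.0,
                             sdn_coef=0.0, pos_sdn_coef=0.0),
            motor_vel_sd=0.0,
        )
        sim = simulate_trial(simple_traj, params, rng)
        assert sim.events == []
        # pursuit approaches gain * target velocity in steady state
        v_e = np.diff(sim.trace.eye_x[-300:]) * 1000.0
        v2_abs = simple_traj.spec.vs1 + simple_traj.spec.vs2
        assert np.median(v_e) == pytest.approx(
            params.pursuit_gain * v2_abs, rel=0.05
        )

    def test_large_step_triggers_saccade_quickly(self, rng):
        from catchup_saccades import StepRampSpec, build_trial

        spec = StepRampSpec(
            fixation_x=-20.0, ps1=-4.0, vs1=20.0, steady_dur=600.0,
            ps2=-15.0, vs2=-16.0, blur=False,  # error grows leftward, |PE_pred| ~ 17
        )
        traj = build_trial(spec)
        hits = 0
        n_runs = 50
        for _ in range(n_runs):
            sim = simulate_trial(traj, ModelParams(), rng)
            step2 = traj.event_times["step2"]
            post = [e for e in sim.events if step2 <= e.onset <= step2 + 400.0]
            hits += bool(post)
        assert hits >= 0.95 * n_runs

    def test_small_predicted_error_yields_more_smooth_trials(self, rng):
        from catchup_saccades import StepRampSpec, build_trial

        def smooth_fraction(ps2, vs2, n=40):
            spec = StepRampSpec(
                fixation_x=-20.0, ps1=-4.0, vs1=20.0, steady_dur=600.0,
                ps2=ps2, vs2=vs2, blur=False,
            )
            traj = build_trial(spec)
            smooth = 0
            for _ in range(n):
                sim = simulate_trial(traj, ModelParams(), rng)
                step2 = traj.event_times["step2"]
                post = [e for e in sim.events if step2 <= e.onset <= step2 + 400.0]
                smooth += not post
            return smooth / n

        # |PE_pred| ~ 0.3 deg vs ~ 11 deg at the step
        assert smooth_fraction(-1.5, 12.0) > smooth_fraction(14.0, -20.0)

    def test_simulation_is_seed_reproducible(self, simple_traj):
        a = simulate_trial(simple_traj, ModelParams(), np.random.default_rng(9))
        b = simulate_trial(simple_traj, ModelParams(), np.random.default_rng(9))
        assert np.array_equal(a.trace.eye_x, b.trace.eye_x)
        assert [e.onset for e in a.events] == [e.onset for e in b.events]
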