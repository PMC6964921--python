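"""Stochastic trigger model for catch-up saccades during smooth pursuit.

The model tracks position error (PE = target - eye) and retinal slip
(RS = target velocity - eye velocity) from noisy delayed observations with a
Kalman filter, linearly extrapolates PE ``dt`` seconds into the future
(PE_pred = PE + dt * RS), converts the resulting Gaussian belief into the
confidence that the target sits outside the fovea, and accumulates that
confidence (a log probability ratio of extrafoveal vs foveal mass) to a
threshold, LATER-style.  Crossing the threshold commits a saccade that is
executed after a fixed motor delay with an amplitude aimed at the predicted
position error at landing; in parallel, a pursuit controller accelerates the
eye toward the estimated target velocity with gain < 1.

Large or growing predicted errors with low uncertainty produce a fast rise
and early saccades; small predicted errors or high uncertainty (blurred
target, signal-dependent noise at high retinal slip) slow the rise, delaying
or suppressing the saccade entirely (a smooth trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DecisionTrace, EyeTrace, SaccadeEvent
from .task_design import TargetTrajectory

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# parameters and state containers


@dataclass(frozen=True)
class NoiseModel:
    """Sensory and process noise magnitudes.

    Position observation noise depends on target appearance (blur widens it);
    velocity observation noise has a signal-dependent component growing with
    |RS| (SDN).  ``process_sd`` is the random-walk diffusion of RS in the
    filter's internal model (deg/s per sqrt(s)); ``pos_process_sd`` is an
    extra random-walk diffusion on PE itself (deg per sqrt(s)) standing in
    for unmodeled target jumps, which keeps the position gain from collapsing
    once the filter has converged.
    """

    pos_sd_clear: float = 0.5
    pos_sd_blur: float = 2.5
    vel_sd_base: float = 1.0
    sdn_coef: float = 0.2
    pos_sdn_coef: float = 0.1  # motion smear: relative growth of pos sd per deg/s of |RS|
    process_sd: float = 30.0
    pos_process_sd: float = 3.0

    def __post_init__(self) -> None:
        vals = (self.pos_sd_clear, self.pos_sd_blur, self.vel_sd_base,
                self.sdn_coef, self.pos_sdn_coef, self.process_sd,
                self.pos_process_sd)
        if any(v < 0 for v in vals):
            raise ValueError("noise magnitudes must be non-negative")
        if self.pos_sd_blur < self.pos_sd_clear:
            raise ValueError("pos_sd_blur must be >= pos_sd_clear")

    def pos_sd(self, blur: bool, rs: float = 0.0) -> float:
        """Position observation sd; grows with |RS| (retinal motion smear).

        The smear is multiplicative: a blurred target degrades both the
        static and the motion-dependent component of localization.
        """
        base = self.pos_sd_blur if blur else self.pos_sd_clear
        return base * (1.0 + self.pos_sdn_coef * abs(rs))

    def vel_sd(self, rs: float) -> float:
        return self.vel_sd_base + self.sdn_coef * abs(rs)


@dataclass
class SensoryEstimate:
    """Gaussian belief over (PE, RS) maintained by the Kalman filter."""

    pe_mean: float
    rs_mean: float
    cov: np.ndarray  # 2x2, (PE, RS)

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2):
            raise ValueError("cov must be 2x2")
        if abs(c[0, 1] - c[1, 0]) > 1e-9 * (1 + abs(c[0, 1])):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-9:
            raise ValueError("cov must be positive semidefinite")
        self.cov = c


@dataclass(frozen=True)
class PredictedError:
    """Gaussian belief over PE extrapolated ``dt`` seconds ahead."""

    mean: float
    var: float
    dt: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance must be non-negative")


@dataclass
class DecisionState:
    """Accumulated confidence and trigger bookkeeping.

    ``elapsed`` counts ms since the last reset; ``triggered_at`` records the
    elapsed time (ms) of the first threshold crossing of this segment.
    """

    evidence: float = 0.0
    threshold: float = 12.0
    elapsed: float = 0.0
    triggered_at: float | None = None

    def reset(self) -> None:
        self.evidence = 0.0
        self.elapsed = 0.0
        self.triggered_at = None


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the trigger model.

    dt: extrapolation horizon (s), plausibility range 0.09-0.29.
    sensory_delay / motor_delay in ms; pursuit_gain in (0, 1];
    pursuit_tc: first-order pursuit time constant (ms);
    threshold: accumulated log-probability-ratio needed to commit a saccade.
    """

    dt: float = 0.15
    foveal_radius: float = 1.5
    threshold: float = 0.75
    threshold_cv: float = 0.2  # lognormal trial-to-trial threshold variability
    leak: float = 0.0  # 1/s, evidence leak (0 = perfect integrator)
    rate_cap: float = 35.0  # 1/s, saturation of the confidence rise rate
    sensory_delay: float = 50.0
    motor_delay: float = 100.0
    pursuit_gain: float = 0.9
    pursuit_tc: float = 100.0
    motor_vel_sd: float = 1.0  # deg/s per sqrt(s), pursuit command diffusion
    saccade_amp_sdn: float = 0.05  # endpoint noise, fraction of amplitude
    saccade_amp_sd0: float = 0.1  # endpoint noise floor, deg
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dt <= 0.5):
            raise ValueError("dt out of range")
        if self.sensory_delay < 0 or self.motor_delay < 0:
            raise ValueError("delays must be non-negative")
        if not (0 < self.pursuit_gain <= 1):
            raise ValueError("pursuit_gain must be in (0, 1]")


# ---------------------------------------------------------------------------
# sensory front end


def observe(
    pe_true: float,
    rs_true: float,
    noise: NoiseModel,
    blur: bool,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one noisy observation of (PE, RS).

    PE noise is Gaussian with the blur- and slip-dependent sd (motion
    smear); RS noise is Gaussian with sd = vel_sd_base + sdn_coef *
    |rs_true| (signal-dependent noise).
    """
    pe_obs = pe_true + noise.pos_sd(blur, rs_true) * rng.standard_normal()
    rs_obs = rs_true + noise.vel_sd(rs_true) * rng.standard_normal()
    return float(pe_obs), float(rs_obs)


def _kf_step(
    pe: float, rs: float, p11: float, p12: float, p22: float,
    z_pe: float, z_rs: float, r_pos: float, r_vel: float,
    h: float, q: float, qp: float = 0.0,
) -> tuple[float, float, float, float, float]:
    """One scalar-arithmetic predict/update step of the (PE, RS) filter.

    Dynamics: PE integrates RS (d PE/dt = RS) plus a random walk with
    diffusion qp (unmodeled target jumps); RS is a random walk with
    diffusion q.  Observation: both components directly, independent
    Gaussian noise with variances r_pos, r_vel.
    """
    # predict
    pe_p = pe + h * rs
    q22 = q * q * h
    q12 = 0.5 * q * q * h * h
    q11 = q * q * h * h * h / 3.0 + qp * qp * h
    p11p = p11 + 2.0 * h * p12 + h * h * p22 + q11
    p12p = p12 + h * p22 + q12
    p22p = p22 + q22
    # update (H = I)
    s11 = p11p + r_pos
    s22 = p22p + r_vel
    s12 = p12p
    det = s11 * s22 - s12 * s12
    k11 = (p11p * s22 - p12p * s12) / det
    k12 = (p12p * s11 - p11p * s12) / det
    k21 = (p12p * s22 - p22p * s12) / det
    k22 = (p22p * s11 - p12p * s12) / det
    y1 = z_pe - pe_p
    y2 = z_rs - rs
    pe_n = pe_p + k11 * y1 + k12 * y2
    rs_n = rs + k21 * y1 + k22 * y2
    a11 = 1.0 - k11
    p11n = a11 * p11p - k12 * p12p
    p12n = a11 * p12p - k12 * p22p
    p21n = -k21 * p11p + (1.0 - k22) * p12p
    p22n = -k21 * p12p + (1.0 - k22) * p22p
    p12n = 0.5 * (p12n + p21n)
    return pe_n, rs_n, p11n, p12n, p22n


def _kf_predict_only(
    pe: float, rs: float, p11: float, p12: float, p22: float, h: float, q: float,
    qp: float = 0.0,
) -> tuple[float, float, float, float, float]:
    """Time update without measurement (vision suppressed, e.g. mid-saccade)."""
    pe_p = pe + h * rs
    p11p = p11 + 2.0 * h * p12 + h * h * p22 + q * q * h * h * h / 3.0 + qp * qp * h
    p12p = p12 + h * p22 + 0.5 * q * q * h * h
    p22p = p22 + q * q * h
    return pe_p, rs, p11p, p12p, p22p


def kalman_update(
    est: SensoryEstimate,
    obs: tuple[float, float],
    noise: NoiseModel,
    dt_step: float,
    blur: bool = False,
) -> SensoryEstimate:
    """Standard predict/update of the (PE, RS) belief for one observation."""
    if dt_step <= 0:
        raise ValueError("dt_step must be positive")
    z_pe, z_rs = obs
    r_pos = noise.pos_sd(blur, z_rs) ** 2
    r_vel = noise.vel_sd(z_rs) ** 2
    pe, rs, p11, p12, p22 = _kf_step(
        est.pe_mean, est.rs_mean,
        float(est.cov[0, 0]), float(est.cov[0, 1]), float(est.cov[1, 1]),
        z_pe, z_rs, r_pos, r_vel, dt_step, noise.process_sd, noise.pos_process_sd,
    )
    return SensoryEstimate(pe, rs, np.array([[p11, p12], [p12, p22]]))


def predict_error(est: SensoryEstimate, dt: float) -> PredictedError:
    """Linear extrapolation of the PE belief: mean PE + dt*RS with propagated variance."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    mean = est.pe_mean + dt * est.rs_mean
    var = float(est.cov[0, 0] + 2.0 * dt * est.cov[0, 1] + dt * dt * est.cov[1, 1])
    return PredictedError(mean=mean, var=max(var, 0.0), dt=dt)


# ---------------------------------------------------------------------------
# decision pathway


def _log_norm_tail(z: float) -> float:
    """log P(Z > z) for standard normal Z, stable for large z."""
    if z < 7.0:
        return math.log(0.5 * math.erfc(z / _SQRT2))
    # asymptotic expansion of the Mills ratio
    z2 = z * z
    return -0.5 * z2 - math.log(z) - _LOG_SQRT_2PI + math.log1p(-1.0 / z2 + 3.0 / (z2 * z2))


def _confidence_terms(mean: float, var: float, r: float) -> tuple[float, float, float]:
    """log P(X > r), log P(X < -r), log P(|X| <= r) for X ~ N(mean, var)."""
    sd = math.sqrt(var)
    log_pr = _log_norm_tail((r - mean) / sd)
    log_pl = _log_norm_tail((mean + r) / sd)
    # foveal mass, computed on whichever side keeps the difference stable
    a = (abs(mean) - r) / sd  # closer fovea edge, in sds
    b = (abs(mean) + r) / sd
    la, lb = _log_norm_tail(a), _log_norm_tail(b)
    log_pin = la + math.log1p(-math.exp(min(lb - la, 0.0)))
    return log_pr, log_pl, log_pin


def confidence_outside_fovea(
    pred: PredictedError, foveal_radius: float
) -> tuple[float, float, float]:
    """Confidence that the predicted target position lies outside the fovea.

    Returns (p_right, p_left, log_ratio) with log_ratio =
    log(max(p_right, p_left) / P(|X| <= r)); computed in log space so that
    very confident beliefs do not underflow.
    """
    if pred.var == 0.0:
        outside = abs(pred.mean) > foveal_radius
        p_right = 1.0 if pred.mean > foveal_radius else 0.0
        p_left = 1.0 if pred.mean < -foveal_radius else 0.0
        return p_right, p_left, math.inf if outside else -math.inf
    log_pr, log_pl, log_pin = _confidence_terms(pred.mean, pred.var, foveal_radius)
    log_ratio = max(log_pr, log_pl) - log_pin
    return math.exp(log_pr), math.exp(log_pl), log_ratio


def confidence_area_ratio(pred: PredictedError, foveal_radius: float) -> float:
    """Alternative confidence read-out: extrafoveal area ratio max(p)/(p_r+p_l+p_in)."""
    p_r, p_l, _ = confidence_outside_fovea(pred, foveal_radius)
    return max(p_r, p_l)


def accumulate_decision(
    state: DecisionState, log_ratio: float, dt_step: float, leak: float = 0.0
) -> DecisionState:
    """Advance the accumulator by one step; the rise rate is the instantaneous confidence.

    ``dt_step`` is in seconds.  Negative increments are floored at zero (no
    decay below start); an optional leak (1/s) lets sustained weak evidence
    saturate below threshold instead of crossing eventually.  Sets
    ``triggered_at`` (ms since the last reset) at the first threshold
    crossing.
    """
    state.evidence += (max(log_ratio, 0.0) - leak * state.evidence) * dt_step
    state.elapsed += dt_step * 1000.0
    if state.triggered_at is None and state.evidence >= state.threshold:
        state.triggered_at = state.elapsed
    return state


# ---------------------------------------------------------------------------
# motor pathway


def saccade_duration_ms(amplitude: float) -> float:
    """Main-sequence duration rule: 2.2 ms/deg * |A| + 21 ms."""
    return 2.2 * abs(amplitude) + 21.0


def min_jerk_displacement(amplitude: float, duration_ms: float, sample_rate: float) -> np.ndarray:
    """Symmetric minimum-jerk displacement profile sampled on the trace grid.

    Integrates to exactly ``amplitude`` at the last sample.
    """
    n = max(int(round(duration_ms * sample_rate / 1000.0)), 2)
    tau = np.linspace(0.0, 1.0, n + 1)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def plan_saccade(est: SensoryEstimate, params: ModelParams, now: float) -> SaccadeEvent:
    """Commit a saccade from the current belief.

    Onset follows the trigger by the motor delay; the amplitude aims at the
    predicted PE at the expected landing time (motor delay plus half the
    saccade duration, one fixed-point pass on the duration rule).
    """
    horizon0 = params.motor_delay / 1000.0
    amp0 = est.pe_mean + horizon0 * est.rs_mean
    dur = saccade_duration_ms(amp0)
    horizon = (params.motor_delay + 0.5 * dur) / 1000.0
    amp = est.pe_mean + horizon * est.rs_mean
    dur = saccade_duration_ms(amp)
    onset = now + params.motor_delay
    return SaccadeEvent(onset=onset, offset=onset + dur, amplitude=amp)


# ---------------------------------------------------------------------------
# closed-loop trial simulation


@dataclass
class SimulatedTrial:
    trace: EyeTrace
    events: list[SaccadeEvent]
    decision: DecisionTrace


def simulate_trial(
    traj: TargetTrajectory,
    params: ModelParams,
    rng: np.random.Generator,
) -> SimulatedTrial:
    """Closed-loop simulation of one trial at the trace sample rate.

    Per sample: delayed noisy observation -> Kalman update -> PE extrapolation
    -> confidence -> accumulation; pursuit accelerates the eye toward
    gain * estimated target velocity with a first-order lag; threshold
    crossings schedule saccades executed as minimum-jerk displacements after
    the motor delay.  The accumulator resets at each target step and after
    each completed saccade; observations are suppressed while a saccade is in
    flight.  Returns the eye trace, executed saccades, and the full
    per-sample decision trace.
    """
    spec = traj.spec
    blur = bool(spec.blur) if spec is not None else False
    fs = traj.sample_rate
    h = 1.0 / fs
    n = traj.t.size
    t = traj.t
    x_t = traj.x
    # analytic target velocity per segment (steps carry no velocity impulse)
    step1 = traj.event_times.get("step1", 0.0)
    step2 = traj.event_times.get("step2", 0.0)
    v_t = np.zeros(n)
    if spec is not None:
        v_t[(t >= step1) & (t < step2)] = spec.vs1
        v_t[t >= step2] = spec.vs1 + spec.vs2  # vs2 is a velocity step
    else:
        v_t[1:] = np.diff(x_t) * fs

    noise = params.noise
    q = noise.process_sd
    qp = noise.pos_process_sd
    delay_k = int(round(params.sensory_delay / 1000.0 * fs))
    step_idx = {int(round(step1 / 1000.0 * fs)), int(round(step2 / 1000.0 * fs))}

    # state
    pe_est, rs_est = 0.0, 0.0
    p11, p12, p22 = 1.0, 0.0, 25.0  # broad prior at trial start
    evidence = 0.0
    x_e = float(x_t[0])  # start on the fixation target
    v_e = 0.0
    pending_onset_i: int | None = None
    pending_amp = 0.0
    sac_profile: np.ndarray | None = None
    sac_i0 = 0
    in_flight_until = -1
    events: list[SaccadeEvent] = []

    pe_hist = np.empty(n)
    rs_hist = np.empty(n)
    flight_mask = np.zeros(n, dtype=bool)  # saccadic suppression at source time
    sacc_disp = np.zeros(n + 1)  # cumulative executed saccadic displacement
    tr_pe = np.empty(n)
    tr_rs = np.empty(n)
    tr_pm = np.empty(n)
    tr_pv = np.empty(n)
    tr_ev = np.empty(n)
    eye = np.empty(n)

    dt = params.dt
    r_fov = params.foveal_radius
    thr = params.threshold
    leak = params.leak
    cap = params.rate_cap if params.rate_cap > 0 else math.inf
    if params.threshold_cv > 0:  # LATER-style across-trial rise variability
        sig = math.sqrt(math.log1p(params.threshold_cv**2))
        thr *= math.exp(sig * rng.standard_normal() - 0.5 * sig * sig)
    kp = 1000.0 / params.pursuit_tc  # 1/s
    gain = params.pursuit_gain
    mv = params.motor_vel_sd * math.sqrt(h)
    normals = rng.standard_normal(3 * n)  # pe, rs, motor per sample
    nrm_i = 0

    for i in range(n):
        # ground-truth errors at this instant
        pe_hist[i] = x_t[i] - x_e
        rs_hist[i] = v_t[i] - v_e

        in_flight = i <= in_flight_until and sac_profile is not None
        if in_flight:
            flight_mask[i] = True

        # --- sensory update on delayed observation; suppressed while a
        # saccade is in flight and for source samples recorded mid-saccade.
        # Corollary discharge corrects the delayed position signal for
        # saccadic displacement executed since the source time.
        j = i - delay_k
        if j >= 0 and not in_flight and not flight_mask[j]:
            pe_true = pe_hist[j] - (sacc_disp[i] - sacc_disp[j])
            rs_true = rs_hist[j]
            pos_sd = noise.pos_sd(blur, rs_true)
            z_pe = pe_true + pos_sd * normals[nrm_i]
            vel_sd = noise.vel_sd(rs_true)
            z_rs = rs_true + vel_sd * normals[nrm_i + 1]
            pe_est, rs_est, p11, p12, p22 = _kf_step(
                pe_est, rs_est, p11, p12, p22,
                z_pe, z_rs, pos_sd * pos_sd, vel_sd * vel_sd, h, q, qp,
            )
        else:
            pe_est, rs_est, p11, p12, p22 = _kf_predict_only(
                pe_est, rs_est, p11, p12, p22, h, q, qp
            )
        nrm_i += 2

        # --- decision variables
        pm = pe_est + dt * rs_est
        pv = max(p11 + 2.0 * dt * p12 + dt * dt * p22, 1e-12)
        if i in step_idx:
            evidence = 0.0  # new perturbation: the first post-step saccade is the event
        if not in_flight and pending_onset_i is None:
            _, _, log_ratio = confidence_outside_fovea(
                PredictedError(pm, pv, dt), r_fov
            )
            if log_ratio > 0.0 or evidence > 0.0:
                rate = min(max(log_ratio, 0.0), cap)
                evidence += (rate - leak * evidence) * h
            if evidence >= thr:
                sac = plan_saccade(
                    SensoryEstimate(pe_est, rs_est, np.array([[p11, p12], [p12, p22]])),
                    params, now=t[i],
                )
                amp_sd = params.saccade_amp_sd0 + params.saccade_amp_sdn * abs(sac.amplitude)
                pending_amp = sac.amplitude + amp_sd * rng.standard_normal()
                pending_onset_i = i + int(round(params.motor_delay / 1000.0 * fs))
                evidence = 0.0

        # --- motor: launch a pending saccade
        if pending_onset_i is not None and i >= pending_onset_i:
            dur = saccade_duration_ms(pending_amp)
            sac_profile = min_jerk_displacement(pending_amp, dur, fs)
            sac_i0 = i
            in_flight_until = i + sac_profile.size - 2  # increments span size-1 samples
            events.append(
                SaccadeEvent(onset=t[i], offset=t[i] + dur, amplitude=pending_amp)
            )
            pending_onset_i = None
            in_flight = True

        # --- pursuit dynamics (continues under the saccade)
        acc = kp * (gain * (rs_est + v_e) - v_e)
        v_e += acc * h + mv * normals[nrm_i]
        nrm_i += 1
        x_e += v_e * h
        sacc_disp[i + 1] = sacc_disp[i]
        if sac_profile is not None and sac_i0 <= i <= in_flight_until:
            k = i - sac_i0
            inc = sac_profile[k + 1] - sac_profile[k]
            x_e += inc
            sacc_disp[i + 1] += inc
            if i == in_flight_until:
                evidence = 0.0  # saccade done: start accumulating afresh
                # efference copy: the internal estimate knows the commanded
                # displacement without waiting for delayed reafference
                pe_est -= sac_profile[-1]

        eye[i] = x_e
        tr_pe[i] = pe_est
        tr_rs[i] = rs_est
        tr_pm[i] = pm
        tr_pv[i] = pv
        tr_ev[i] = evidence
        if not np.isfinite(x_e):
            raise FloatingPointError("eye trace became non-finite")

    trace = EyeTrace(
        time=t.copy(), target_x=x_t.copy(), eye_x=eye,
        condition="blur" if blur else "clear",
        step2_time=step2, spec=spec,
        trial_id=spec.trial_id if spec is not None else 0,
    )
    decision = DecisionTrace(
        time=t.copy(), pe_est=tr_pe, rs_est=tr_rs,
        pe_pred_mean=tr_pm, pe_pred_var=tr_pv, evidence=tr_ev,
    )
    return SimulatedTrial(trace=trace, events=events, decision=decision)
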