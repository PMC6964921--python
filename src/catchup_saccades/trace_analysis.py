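"""Per-trial analysis chain for pursuit/saccade eye traces.

Mirrors standard oculomotor preprocessing: zero-phase low-pass filtering of
position (Butterworth, 50 Hz cutoff), central-difference differentiation to
velocity and acceleration, saccade detection by a 750 deg/s^2 acceleration
threshold with onset/offset refinement, trial exclusion rules (blinks/missing
data in the critical window, saccade in flight at the second target step,
double saccades, saccades made opposite the outstanding error), and the
per-trial metrics: PE, RS, PE_pred = PE + dt*RS, eye-crossing time
T_xe = -PE/RS, target-crossing time T_xt = -PS/VS, trigger time, and the
early/late/smooth classification (175-ms and 400-ms cutoffs).

Coordinates: degrees, rightward positive; time in ms from trial start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .core import EyeTrace, SaccadeEvent


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the analysis chain (defaults are the study's values)."""

    dt: float = 0.15  # s, PE extrapolation horizon
    filter_cutoff_hz: float = 50.0
    filter_order: int = 2
    acc_threshold: float = 750.0  # deg/s^2
    merge_gap_ms: float = 20.0
    double_sacc_isi_ms: float = 100.0
    saccade_window_ms: float = 400.0  # smooth-trial window after step2
    early_cutoff_ms: float = 175.0
    presacc_lead_ms: float = 100.0
    step_window_ms: float = 50.0  # PE_pred averaging window at target step
    rs_eps: float = 1e-6  # |RS| below this makes T_xe undefined
    direction_pe_min: float = 0.5  # deg, minimum |PE| to judge saccade direction


# ---------------------------------------------------------------------------
# signal conditioning


def lowpass_zero_phase(
    series: np.ndarray,
    cutoff: float = 50.0,
    fs: float = 1000.0,
    order: int = 2,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    NaN samples are bridged by linear interpolation for filtering and
    restored afterwards, so gaps stay visible to the exclusion rules.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3 * (2 * order + 1):
        raise ValueError("series too short for zero-phase filtering")
    b, a = butter(order, cutoff, fs=fs)
    nan_mask = np.isnan(x)
    if nan_mask.all():
        return x.copy()
    if nan_mask.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], x[~nan_mask])
    y = filtfilt(b, a, x)
    if nan_mask.any():
        y[nan_mask] = np.nan
    return y


def differentiate_central(series: np.ndarray, rate: float = 1000.0) -> np.ndarray:
    """Central-difference derivative; one-sided at the endpoints.

    Exact for linear (velocity) and, applied twice, for quadratic signals.
    NaNs propagate through the stencil (a NaN at i makes i-1 and i+1 NaN).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * rate / 2.0
    v[0] = (x[1] - x[0]) * rate
    v[-1] = (x[-1] - x[-2]) * rate
    return v


# ---------------------------------------------------------------------------
# saccade detection


def _refine_edge(
    vel: np.ndarray, i: int, direction: float, step: int, min_slope: float = 0.3
) -> int:
    """Walk from i in ``step`` direction while signed velocity keeps falling.

    The walk stops once the per-sample decrease drops below ``min_slope``
    (deg/s per sample, i.e. an acceleration floor), so it ends at the foot of
    the saccadic velocity transient instead of drifting down the much
    shallower pursuit ramp.
    """
    n = vel.size
    j = i
    while 0 < j + step < n - 1:
        a, b = direction * vel[j + step], direction * vel[j]
        if not (np.isfinite(a) and np.isfinite(b)) or b - a < min_slope:
            break
        j += step
    return j


def detect_saccades(
    time: np.ndarray,
    eye_x: np.ndarray,
    vel: np.ndarray,
    acc: np.ndarray,
    threshold: float = 750.0,
    merge_gap_ms: float = 20.0,
    min_dur_ms: float = 10.0,
) -> list[SaccadeEvent]:
    """Detect saccades where |acceleration| exceeds ``threshold``.

    Suprathreshold spans closer than ``merge_gap_ms`` are merged; onset and
    offset are refined outwards to the nearest velocity minimum along the
    saccade's direction; amplitude is the eye displacement offset - onset.
    Events shorter than ``min_dur_ms`` are filter-ringing artifacts and are
    dropped (the main-sequence duration of even a tiny saccade exceeds 20 ms).
    """
    fs = 1000.0 / (time[1] - time[0])
    above = np.abs(acc) > threshold
    above &= np.isfinite(acc)
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    # merge spans separated by short gaps
    gap = int(round(merge_gap_ms / 1000.0 * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events: list[SaccadeEvent] = []
    for s, e in merged:
        # direction = sign of the velocity excursion from the pre-event
        # pursuit baseline (net displacement misleads for a small saccade
        # riding on fast opposite-direction pursuit)
        base = np.nanmedian(vel[max(s - 25, 0) : max(s - 5, 1)])
        if not np.isfinite(base):
            base = 0.0
        exc = vel[s : e + 1] - base
        k = int(np.nanargmax(np.abs(exc)))
        direction = 1.0 if exc[k] >= 0 else -1.0
        lo = _refine_edge(vel, s, direction, step=-1)
        hi = _refine_edge(vel, e, direction, step=+1)
        if hi <= lo:
            continue
        # the zero-phase filter smears the transient symmetrically, so the
        # flanking velocity minima fall slightly outside the true event;
        # take the 5%-of-peak velocity crossings between them as the edges
        seg = direction * (vel[lo : hi + 1] - direction * min(direction * vel[lo], direction * vel[hi]))
        peak = np.nanmax(seg)
        if peak <= 0:
            continue
        edge = np.flatnonzero(seg >= 0.05 * peak)
        onset_i = lo + int(edge[0])
        offset_i = lo + int(edge[-1])
        if offset_i <= onset_i or (offset_i - onset_i) < min_dur_ms / 1000.0 * fs:
            continue
        amp = float(eye_x[offset_i] - eye_x[onset_i])
        events.append(
            SaccadeEvent(
                onset=float(time[onset_i]), offset=float(time[offset_i]), amplitude=amp
            )
        )
    events.sort(key=lambda ev: ev.onset)
    return events


# ---------------------------------------------------------------------------
# error signals and metrics


def compute_txt(ps2: float, vs2: float) -> float:
    """Target-crossing time -PS/VS, ms; NaN when VS = 0 (undefined)."""
    if vs2 == 0:
        return float("nan")
    return -ps2 / vs2 * 1000.0


def compute_txe(pe: float, rs: float, rs_eps: float = 1e-6) -> float:
    """Eye-crossing time -PE/RS, ms; NaN when |RS| ~ 0 (undefined marker)."""
    if not np.isfinite(rs) or abs(rs) <= rs_eps:
        return float("nan")
    return -pe / rs * 1000.0


def compute_pe_pred(pe, rs, dt: float = 0.15):
    """Predicted position error PE + dt*RS (deg); works on scalars or arrays."""
    return pe + dt * np.asarray(rs) if np.ndim(rs) else pe + dt * rs


def compute_errors(
    trace: EyeTrace, config: AnalysisConfig = AnalysisConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Position error (target - eye) and retinal slip (target vel - eye vel).

    Eye position is low-pass filtered and differentiated; the target channel
    is the commanded trajectory, so its velocity comes from the trial spec
    segments when available (differentiating a position step would inject a
    spurious velocity impulse), else from the central difference with the
    step samples masked.
    """
    fs = trace.sample_rate
    eye_f = lowpass_zero_phase(
        trace.eye_x, cutoff=config.filter_cutoff_hz, fs=fs, order=config.filter_order
    )
    eye_v = differentiate_central(eye_f, fs)
    pe = trace.target_x - eye_f
    spec = trace.spec
    if spec is not None:
        v_t = np.zeros(trace.time.size)
        step2 = trace.step2_time
        step1 = step2 - spec.steady_dur
        v_t[(trace.time >= step1) & (trace.time < step2)] = spec.vs1
        v_t[trace.time >= step2] = spec.vs1 + spec.vs2  # vs2 is a velocity step
    else:
        v_t = differentiate_central(trace.target_x, fs)
        spike = np.abs(v_t) > 300.0  # position-step artifacts
        v_t[spike] = np.nan
    rs = v_t - eye_v
    return pe, rs


def apply_exclusions(
    trace: EyeTrace,
    events: list[SaccadeEvent],
    pe: np.ndarray | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[bool, str]:
    """Trial exclusion rules; returns (keep, reason).

    Excludes: NaN gaps (blinks / lost pupil) during or after the second
    target step; a saccade in flight at the second step; double saccades
    (post-step2 inter-saccadic interval under the configured 100 ms); and a
    first post-step2 saccade directed against the outstanding position error
    (a saccade made to the first ramp's trajectory).
    """
    step2 = trace.step2_time
    after = trace.time >= step2 - config.step_window_ms
    if np.isnan(trace.eye_x[after]).any():
        return False, "blink"
    for ev in events:
        if ev.onset <= step2 <= ev.offset:
            return False, "saccade_at_step"
    post = [ev for ev in events if ev.onset >= step2]
    # double saccades: rapid pairs contaminating the analyzed first saccade
    # (pairs starting after the classification window leave it untouched)
    for prev, nxt in zip(post, post[1:]):
        if prev.onset - step2 > config.saccade_window_ms:
            break
        if nxt.onset - prev.offset < config.double_sacc_isi_ms:
            return False, "double_saccade"
    if post and pe is not None:
        first = post[0]
        fs = trace.sample_rate
        i = int(round((first.onset - config.presacc_lead_ms - trace.time[0]) / 1000.0 * fs))
        i = max(i, int(round((step2 - trace.time[0]) / 1000.0 * fs)))
        if 0 <= i < pe.size and np.isfinite(pe[i]):
            if abs(pe[i]) > config.direction_pe_min and np.sign(first.amplitude) != np.sign(pe[i]):
                return False, "wrong_direction"
    return True, "ok"


def pe_pred_at_step(
    pe_pred: np.ndarray,
    time: np.ndarray,
    step2: float,
    window: float = 50.0,
) -> float:
    """Mean predicted position error over [step2, step2 + window) ms."""
    sel = (time >= step2) & (time < step2 + window)
    return float(np.nanmean(pe_pred[sel]))


def sample_presaccadic(
    pe: np.ndarray,
    rs: np.ndarray,
    time: np.ndarray,
    onset: float | None,
    step2: float,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[float, float, float, float, bool]:
    """Pre-saccadic sensory sample: PE, RS, PE_pred, T_xe (+ clipped flag).

    For saccade trials, instantaneous values ``presacc_lead_ms`` before
    onset (clipped to step2 and flagged if the lead reaches back past the
    step).  For smooth trials (onset None), PE and RS are averaged over the
    400-ms window after the step instead.
    """
    fs = 1000.0 / (time[1] - time[0])
    if onset is None:
        sel = (time >= step2) & (time < step2 + config.saccade_window_ms)
        pe_s = float(np.nanmean(pe[sel]))
        rs_s = float(np.nanmean(rs[sel]))
        clipped = False
    else:
        t_s = onset - config.presacc_lead_ms
        clipped = t_s < step2
        t_s = max(t_s, step2)
        i = int(round((t_s - time[0]) / 1000.0 * fs))
        i = min(max(i, 0), pe.size - 1)
        pe_s, rs_s = float(pe[i]), float(rs[i])
    pp = compute_pe_pred(pe_s, rs_s, config.dt)
    return pe_s, rs_s, float(pp), compute_txe(pe_s, rs_s, config.rs_eps), clipped


def classify_trial(
    trigger_time: float | None,
    window: float = 400.0,
    early_cutoff: float = 175.0,
) -> str:
    """early (< 175 ms), late (175-400 ms), or smooth (no saccade within 400 ms)."""
    if trigger_time is None or trigger_time >= window:
        return "smooth"
    return "early" if trigger_time < early_cutoff else "late"


# ---------------------------------------------------------------------------
# per-trial driver


def analyze_trial(trace: EyeTrace, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run the full chain on one trace; returns one metrics row (dict)."""
    fs = trace.sample_rate
    eye_f = lowpass_zero_phase(
        trace.eye_x, cutoff=config.filter_cutoff_hz, fs=fs, order=config.filter_order
    )
    vel = differentiate_central(eye_f, fs)
    acc = differentiate_central(vel, fs)
    events = detect_saccades(
        trace.time, eye_f, vel, acc,
        threshold=config.acc_threshold, merge_gap_ms=config.merge_gap_ms,
    )
    pe, rs = compute_errors(trace, config)
    keep, reason = apply_exclusions(trace, events, pe, config)
    step2 = trace.step2_time
    post = [ev for ev in events if ev.onset >= step2]
    for k, ev in enumerate(post):
        ev.index_after_step2 = k
    trigger_time = post[0].onset - step2 if post else None
    klass = classify_trial(trigger_time, config.saccade_window_ms, config.early_cutoff_ms)
    pe_pred = compute_pe_pred(pe, rs, config.dt)
    pp_step = pe_pred_at_step(pe_pred, trace.time, step2, config.step_window_ms)
    onset = post[0].onset if (post and klass != "smooth") else None
    pe_s, rs_s, pp_s, txe_s, clipped = sample_presaccadic(
        pe, rs, trace.time, onset, step2, config
    )
    spec = trace.spec
    row = {
        "trial_id": trace.trial_id,
        "participant_id": trace.participant_id,
        "condition": trace.condition,
        "ps2": spec.ps2 if spec else np.nan,
        "vs2": spec.vs2 if spec else np.nan,
        "txt": compute_txt(spec.ps2, spec.vs2) if spec else np.nan,
        "excluded": not keep,
        "reason": reason,
        "trigger_time": np.nan if trigger_time is None else trigger_time,
        "klass": klass,
        "pe_pred_at_step": pp_step,
        "pe_presacc": pe_s,
        "rs_presacc": rs_s,
        "pe_pred_presacc": pp_s,
        "txe_presacc": txe_s,
        "presacc_clipped": clipped,
        "n_saccades_post": len(post),
        "first_amp": post[0].amplitude if post else np.nan,
    }
    return row


METRIC_COLUMNS = [
    "trial_id", "participant_id", "condition", "ps2", "vs2", "txt", "excluded",
    "reason", "trigger_time", "klass", "pe_pred_at_step", "pe_presacc",
    "rs_presacc", "pe_pred_presacc", "txe_presacc", "presacc_clipped",
    "n_saccades_post", "first_amp",
]


def analyze_dataset(traces, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Metrics table with one row per trial (excluded trials keep their reason)."""
    rows = [analyze_trial(tr, config) for tr in traces]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def exclusion_report(metrics: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of excluded trials by reason."""
    counts = metrics.groupby("reason").size().rename("n").reset_index()
    counts["fraction"] = counts["n"] / len(metrics)
    return counts.sort_values("n", ascending=False).reset_index(drop=True)
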