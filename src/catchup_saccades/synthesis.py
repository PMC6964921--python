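"""Synthetic labeled eye traces for pipeline testing.

Two generation modes:

* ``model`` — trials are simulated closed-loop by the stochastic trigger
  model (:func:`catchup_saccades.trigger_model.simulate_trial`); ground truth
  is whatever the model executed.
* ``scripted`` — pursuit is synthesized as a first-order lag on the target
  velocity and saccades are placed by a fixed deterministic rule with known
  onsets/amplitudes.  The scripted rule is plumbing, not a scientific claim:
  it exists so detector and metrics can be validated against exact truth.

Both modes can inject blinks (100-300 ms NaN gaps) and isolated NaN dropouts
to exercise the exclusion rules.  Datasets serialize as one CSV per trial
(time_ms, target_x_deg, eye_x_deg; NaN for missing) plus a JSON manifest and
truth log, and regenerate bit-identically from the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EyeTrace, SaccadeEvent
from .task_design import (
    StepRampSpec,
    TargetTrajectory,
    build_session_schedule,
    build_trial,
    schedule_trial_specs,
)
from .trigger_model import (
    ModelParams,
    min_jerk_displacement,
    saccade_duration_ms,
    simulate_trial,
)


@dataclass
class TrialTruth:
    """Ground-truth events of one synthetic trial."""

    trial_id: int
    saccades: list[SaccadeEvent] = field(default_factory=list)
    pursuit_latency: float = 100.0  # ms
    pursuit_gain: float = 0.9
    blink_windows: list[tuple[float, float]] = field(default_factory=list)  # ms
    dropout_times: list[float] = field(default_factory=list)  # ms

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "saccades": [
                {"onset": s.onset, "offset": s.offset, "amplitude": s.amplitude}
                for s in self.saccades
            ],
            "pursuit_latency": self.pursuit_latency,
            "pursuit_gain": self.pursuit_gain,
            "blink_windows": [list(w) for w in self.blink_windows],
            "dropout_times": list(self.dropout_times),
        }


@dataclass
class GroundTruthLog:
    """Per-trial scripted events; invariant: saccades within bounds, non-overlapping."""

    trials: dict[int, TrialTruth] = field(default_factory=dict)

    def add(self, truth: TrialTruth) -> None:
        self.trials[truth.trial_id] = truth


@dataclass
class SyntheticDataset:
    """A full labeled synthetic experiment: traces + truth + provenance."""

    traces: list[EyeTrace]
    truth: GroundTruthLog
    seed: int
    mode: str = "scripted"
    participant_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scripted pursuit and saccade placement


def synthesize_pursuit(
    traj: TargetTrajectory,
    latency: float = 100.0,
    gain: float = 0.9,
    motor_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    tc_ms: float = 80.0,
) -> EyeTrace:
    """First-order pursuit response to the delayed target velocity.

    Eye velocity relaxes toward gain * target velocity delayed by ``latency``
    with time constant ``tc_ms``; eye position is the integral.  Gaussian
    motor noise (``motor_sd`` deg/s per sqrt(s)) diffuses the velocity.
    Steady-state retinal slip on a ramp is (1 - gain) * target velocity.
    """
    if latency < 0:
        raise ValueError("latency must be non-negative")
    if not (0 < gain <= 1):
        raise ValueError("gain must be in (0, 1]")
    fs = traj.sample_rate
    h = 1.0 / fs
    n = traj.t.size
    t = traj.t
    spec = traj.spec
    step1 = traj.event_times.get("step1", 0.0)
    step2 = traj.event_times.get("step2", 0.0)
    v_t = np.zeros(n)
    if spec is not None:
        v_t[(t >= step1) & (t < step2)] = spec.vs1
        v_t[t >= step2] = spec.vs1 + spec.vs2  # vs2 is a velocity step
    else:
        v_t[1:] = np.diff(traj.x) * fs

    k = int(round(latency / 1000.0 * fs))
    v_cmd = np.zeros(n)
    v_cmd[k:] = v_t[: n - k] if k > 0 else v_t
    alpha = h * 1000.0 / tc_ms
    noise = (
        motor_sd * np.sqrt(h) * rng.standard_normal(n)
        if (rng is not None and motor_sd > 0)
        else np.zeros(n)
    )
    v_e = np.empty(n)
    v = 0.0
    for i in range(n):
        v += alpha * (gain * v_cmd[i] - v) + noise[i]
        v_e[i] = v
    x_e = traj.x[0] + np.concatenate(([0.0], np.cumsum(v_e[:-1]) * h))
    return EyeTrace(
        time=t.copy(), target_x=traj.x.copy(), eye_x=x_e,
        condition="blur" if (spec is not None and spec.blur) else "clear",
        step2_time=step2, spec=spec,
        trial_id=spec.trial_id if spec is not None else 0,
    )


def inject_saccade(trace: EyeTrace, onset: float, amplitude: float) -> EyeTrace:
    """Add a minimum-jerk saccade displacement to the eye trace in place.

    Duration follows the main-sequence rule; raises if the saccade overlaps
    a previously injected one (tracked via an attribute on the trace) or
    runs past the end of the trace.
    """
    if amplitude == 0.0:
        return trace
    fs = trace.sample_rate
    dur = saccade_duration_ms(amplitude)
    if onset < trace.time[0] or onset + dur > trace.time[-1]:
        raise ValueError("saccade does not fit within the trace")
    injected: list[tuple[float, float]] = getattr(trace, "_injected_spans", [])
    for lo, hi in injected:
        if onset < hi and onset + dur > lo:
            raise ValueError("saccade overlaps a previously injected saccade")
    i0 = int(round((onset - trace.time[0]) / 1000.0 * fs))
    prof = min_jerk_displacement(amplitude, dur, fs)
    i1 = i0 + prof.size - 1
    trace.eye_x[i0 : i1 + 1] += prof
    trace.eye_x[i1 + 1 :] += amplitude
    injected.append((onset, onset + dur))
    trace._injected_spans = injected  # type: ignore[attr-defined]
    return trace


def scripted_trigger_time(
    spec: StepRampSpec,
    dt: float = 0.15,
    base_ms: float = 180.0,
    scale_ms: float = 250.0,
) -> float | None:
    """Deterministic trigger rule for scripted mode (plumbing, not a model claim).

    Trigger time after step2 shrinks with the magnitude of the predicted
    error of the second step-ramp (PS + dt*VS): base + scale/|PE_pred|.
    Returns None (smooth trial) when |PE_pred| < 1 deg.
    """
    pe_pred = spec.ps2 + dt * spec.vs2
    if abs(pe_pred) < 1.0:
        return None
    return base_ms + scale_ms / abs(pe_pred)


def inject_blink(trace: EyeTrace, start: float, duration: float) -> None:
    """NaN out a [start, start+duration] ms window of the eye channel."""
    fs = trace.sample_rate
    i0 = max(int(round((start - trace.time[0]) / 1000.0 * fs)), 0)
    i1 = min(i0 + int(round(duration / 1000.0 * fs)), trace.eye_x.size - 1)
    trace.eye_x[i0 : i1 + 1] = np.nan


# ---------------------------------------------------------------------------
# dataset generation


@dataclass(frozen=True)
class DatasetConfig:
    """Size, noise and fault rates of a synthetic dataset."""

    n_participants: int = 1
    n_sessions: int = 2
    blocks_per_session: int = 1
    trials_per_block: int = 25
    pursuit_latency: float = 100.0
    pursuit_gain: float = 0.9
    motor_sd: float = 1.0  # deg/s per sqrt(s), scripted mode
    blink_rate: float = 0.0  # per-trial probability of a blink near step2
    dropout_rate: float = 0.0  # per-trial probability of isolated NaN samples
    jitter_sd: float = 0.0  # ms, scripted trigger time jitter
    discrete_ps: bool = False
    post_step2_dur: float = 1200.0


def _scripted_trial(
    spec: StepRampSpec,
    cfg: DatasetConfig,
    rng: np.random.Generator,
) -> tuple[EyeTrace, TrialTruth]:
    traj = build_trial(spec, post_step2_dur=cfg.post_step2_dur)
    trace = synthesize_pursuit(
        traj, latency=cfg.pursuit_latency, gain=cfg.pursuit_gain,
        motor_sd=cfg.motor_sd, rng=rng,
    )
    truth = TrialTruth(
        trial_id=spec.trial_id,
        pursuit_latency=cfg.pursuit_latency,
        pursuit_gain=cfg.pursuit_gain,
    )
    trig = scripted_trigger_time(spec)
    if trig is not None:
        if cfg.jitter_sd > 0:
            trig += float(rng.normal(0.0, cfg.jitter_sd))
        onset = traj.event_times["step2"] + trig
        # aim at the position error outstanding at onset
        fs = trace.sample_rate
        i_on = int(round(onset / 1000.0 * fs))
        if 0 < i_on < trace.time.size - 120:
            amp = float(trace.target_x[i_on] - trace.eye_x[i_on])
            if abs(amp) >= 0.2:
                inject_saccade(trace, onset=trace.time[i_on], amplitude=amp)
                truth.saccades.append(
                    SaccadeEvent(
                        onset=trace.time[i_on],
                        offset=trace.time[i_on] + saccade_duration_ms(amp),
                        amplitude=amp,
                    )
                )
    return trace, truth


def _model_trial(
    spec: StepRampSpec,
    params: ModelParams,
    cfg: DatasetConfig,
    rng: np.random.Generator,
) -> tuple[EyeTrace, TrialTruth]:
    traj = build_trial(spec, post_step2_dur=cfg.post_step2_dur)
    sim = simulate_trial(traj, params, rng)
    truth = TrialTruth(
        trial_id=spec.trial_id,
        pursuit_latency=params.sensory_delay,
        pursuit_gain=params.pursuit_gain,
        saccades=list(sim.events),
    )
    return sim.trace, truth


def generate_dataset(
    config: DatasetConfig,
    mode: str = "scripted",
    rng: np.random.Generator | int | None = None,
    model_params: ModelParams | None = None,
) -> SyntheticDataset:
    """Generate a labeled synthetic dataset.

    ``mode='model'`` runs the closed-loop trigger model per trial;
    ``mode='scripted'`` places saccades by the deterministic rule.  Blinks
    and dropouts are injected at the configured per-trial rates (blinks span
    100-300 ms and are placed in the critical window around step2 so the
    exclusion rules fire).
    """
    if mode not in ("model", "scripted"):
        raise ValueError("mode must be 'model' or 'scripted'")
    seed = rng if isinstance(rng, int) else 0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if model_params is None:
        model_params = ModelParams()

    traces: list[EyeTrace] = []
    truth_log = GroundTruthLog()
    participant_ids = []
    tid = 0
    for p in range(config.n_participants):
        participant_ids.append(p)
        schedule = build_session_schedule(
            p, n_sessions=config.n_sessions,
            blocks_per_session=config.blocks_per_session,
            trials_per_block=config.trials_per_block,
        )
        specs = schedule_trial_specs(schedule, rng, discrete_ps=config.discrete_ps)
        for spec in specs:
            spec = StepRampSpec(**{**spec.to_dict(), "trial_id": tid})
            if mode == "model":
                trace, truth = _model_trial(spec, model_params, config, rng)
            else:
                trace, truth = _scripted_trial(spec, config, rng)
            trace.participant_id = p
            trace.trial_id = tid
            truth.trial_id = tid
            if config.blink_rate > 0 and rng.random() < config.blink_rate:
                dur = float(rng.uniform(100.0, 300.0))
                start = trace.step2_time + float(rng.uniform(-50.0, 200.0))
                inject_blink(trace, start, dur)
                truth.blink_windows.append((start, start + dur))
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                i = int(rng.integers(0, trace.eye_x.size))
                trace.eye_x[i] = np.nan
                truth.dropout_times.append(float(trace.time[i]))
            traces.append(trace)
            truth_log.add(truth)
            tid += 1
    return SyntheticDataset(
        traces=traces, truth=truth_log, seed=seed, mode=mode,
        participant_ids=participant_ids,
    )


# ---------------------------------------------------------------------------
# on-disk format: one CSV per trial + JSON manifest + truth log


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": dataset.seed, "mode": dataset.mode, "trials": []}
    for trace in dataset.traces:
        fname = f"trial_{trace.trial_id:05d}.csv"
        trace.to_frame().to_csv(out / fname, index=False, float_format="%.6f")
        manifest["trials"].append(
            {
                "file": fname,
                "trial_id": trace.trial_id,
                "participant_id": trace.participant_id,
                "condition": trace.condition,
                "step2_time": trace.step2_time,
                "spec": trace.spec.to_dict() if trace.spec is not None else None,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {str(k): v.to_dict() for k, v in dataset.truth.trials.items()}, fh, indent=1
        )


def read_dataset(in_dir, strict: bool = True) -> SyntheticDataset:
    """Load a dataset directory.

    With ``strict=False`` unreadable trial files are skipped and their ids
    collected on the returned dataset's ``skipped_trials`` attribute instead
    of aborting the load.
    """
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    truth_log = GroundTruthLog()
    truth_path = src / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            for k, v in json.load(fh).items():
                truth_log.add(
                    TrialTruth(
                        trial_id=int(k),
                        saccades=[
                            SaccadeEvent(s["onset"], s["offset"], s["amplitude"])
                            for s in v["saccades"]
                        ],
                        pursuit_latency=v["pursuit_latency"],
                        pursuit_gain=v["pursuit_gain"],
                        blink_windows=[tuple(w) for w in v["blink_windows"]],
                        dropout_times=v["dropout_times"],
                    )
                )
    traces = []
    skipped: list[int] = []
    for entry in manifest["trials"]:
        try:
            df = pd.read_csv(src / entry["file"])
            if not {"time_ms", "target_x_deg", "eye_x_deg"} <= set(df.columns):
                raise ValueError("missing trace columns")
        except Exception:
            if strict:
                raise
            skipped.append(entry["trial_id"])
            continue
        spec = StepRampSpec(**entry["spec"]) if entry["spec"] else None
        traces.append(
            EyeTrace(
                time=df["time_ms"].to_numpy(),
                target_x=df["target_x_deg"].to_numpy(),
                eye_x=df["eye_x_deg"].to_numpy(),
                condition=entry["condition"],
                step2_time=entry["step2_time"],
                spec=spec,
                trial_id=entry["trial_id"],
                participant_id=entry["participant_id"],
            )
        )
    ds = SyntheticDataset(
        traces=traces, truth=truth_log, seed=manifest.get("seed", 0),
        mode=manifest.get("mode", "scripted"),
    )
    ds.skipped_trials = skipped  # type: ignore[attr-defined]
    return ds


def load_published_dataset(path):  # pragma: no cover - documented stub
    """Adapter stub for the published human dataset (optional download).

    The deposit's on-disk layout is not machine-documented; users who fetch
    it should convert trials to the CSV-per-trial format of
    :func:`write_dataset` and load them with :func:`read_dataset`.
    """
    raise NotImplementedError(
        "Human-data loading is optional: convert the deposit to the documented "
        "CSV-per-trial layout and use read_dataset()."
    )
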