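"""Double step-ramp task: trial specifications, session schedules, target trajectories.

The task probes catch-up saccade triggering during sustained smooth pursuit.
Each trial starts with eccentric fixation, then a first step-ramp (position
step away from screen center, ramp back toward it, Rashbass-style) to induce
steady-state pursuit, and after a variable steady period a second step-ramp
with a wide range of position steps (PS) and velocity steps (VS).  The second
step is the analyzed perturbation.

Conventions: rightward is positive, positions in degrees of visual angle,
velocities in deg/s, time in ms from trial start.  The sign of the first
position step is away from screen center and its ramp velocity points back
toward center; the second step-ramp is unconstrained in direction apart from
the time-to-foveate bound |PS/VS| <= 1 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

PS1_MAGNITUDES = (2.0, 4.0, 6.0)
VS1_MAGNITUDES = (10.0, 20.0, 30.0)
STEADY_DUR_RANGE_MS = (500.0, 700.0)
VS2_RANGE = (-50.0, 50.0)
PS2_LIMIT = 20.0
MAX_TTF_S = 1.0
SCREEN_HALF_WIDTH_DEG = 30.0
FIXATION_ECCENTRICITY_DEG = 20.0

#: discrete grid used by the optional discrete PS2 mode (2-deg spacing)
PS2_DISCRETE_STEP = 2.0

Condition = Literal["clear", "blur"]


@dataclass(frozen=True)
class StepRampSpec:
    """Stimulus parameters of one double step-ramp trial."""

    fixation_x: float
    ps1: float
    vs1: float
    steady_dur: float  # ms between step1 and step2
    ps2: float  # position step at step2 (deg)
    vs2: float  # velocity *step* at step2 (deg/s, added to the running ramp)
    blur: bool = False
    trial_id: int = 0
    block: int = 0
    session: int = 0

    def __post_init__(self) -> None:
        if abs(self.ps1) not in PS1_MAGNITUDES:
            raise ValueError(f"|ps1| must be one of {PS1_MAGNITUDES}, got {self.ps1}")
        if abs(self.vs1) not in VS1_MAGNITUDES:
            raise ValueError(f"|vs1| must be one of {VS1_MAGNITUDES}, got {self.vs1}")
        if not (STEADY_DUR_RANGE_MS[0] <= self.steady_dur <= STEADY_DUR_RANGE_MS[1]):
            raise ValueError(f"steady_dur outside {STEADY_DUR_RANGE_MS}: {self.steady_dur}")
        if self.vs2 != 0 and abs(self.ps2 / self.vs2) > MAX_TTF_S + 1e-12:
            raise ValueError("second step-ramp violates |ps2/vs2| <= 1 s")
        if abs(self.ps2) > PS2_LIMIT:
            raise ValueError(f"|ps2| must be <= {PS2_LIMIT}")

    @property
    def txt_ms(self) -> float:
        """Target-crossing time -PS/VS of the second step-ramp, in ms."""
        if self.vs2 == 0:
            return float("nan")
        return -self.ps2 / self.vs2 * 1000.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered clear/blur sessions for one participant."""

    participant_id: int
    sessions: tuple  # of (condition, n_blocks, trials_per_block)
    counterbalance_start: bool  # True -> first session blurred

    @property
    def n_trials(self) -> int:
        return sum(b * t for _, b, t in self.sessions)


@dataclass
class TargetTrajectory:
    """Target position sampled on a uniform grid, with step-event times."""

    t: np.ndarray  # ms
    x: np.ndarray  # deg
    event_times: dict = field(default_factory=dict)  # trial_start, step1, step2
    spec: StepRampSpec | None = None

    @property
    def sample_rate(self) -> float:
        return 1000.0 / (self.t[1] - self.t[0])


def draw_second_step(
    rng: np.random.Generator,
    max_ttf: float = MAX_TTF_S,
    discrete_ps: bool = False,
) -> tuple[float, float]:
    """Draw the second step-ramp (ps2, vs2).

    vs2 ~ U(-50, 50) deg/s; ps2 is drawn given vs2 from the admissible
    interval [-20, 20] intersected with |ps2/vs2| <= max_ttf, i.e. the
    time-to-foveate of the second step stays under ``max_ttf`` seconds.
    With ``discrete_ps`` the position step is drawn from the 2-deg grid
    inside that interval instead of the continuous interval.
    """
    if max_ttf <= 0:
        raise ValueError("max_ttf must be positive")
    for _ in range(10_000):
        vs2 = float(rng.uniform(*VS2_RANGE))
        if vs2 == 0.0:
            continue
        lim = min(PS2_LIMIT, abs(vs2) * max_ttf)
        if discrete_ps:
            grid = np.arange(-PS2_LIMIT, PS2_LIMIT + 1e-9, PS2_DISCRETE_STEP)
            grid = grid[np.abs(grid) <= lim + 1e-12]
            if grid.size == 0:
                continue
            ps2 = float(rng.choice(grid))
        else:
            ps2 = float(rng.uniform(-lim, lim))
        return ps2, vs2
    raise RuntimeError("rejection sampling for the second step-ramp failed 10^4 times")


def draw_trial_spec(
    rng: np.random.Generator,
    blur: bool,
    trial_id: int = 0,
    block: int = 0,
    session: int = 0,
    discrete_ps: bool = False,
) -> StepRampSpec:
    """Draw a full trial: fixation side, first step-ramp, steady period, second step-ramp."""
    side = 1.0 if rng.random() < 0.5 else -1.0
    fixation_x = side * FIXATION_ECCENTRICITY_DEG
    # first step away from center (sign of fixation side), ramp back toward center
    ps1 = side * float(rng.choice(PS1_MAGNITUDES))
    vs1 = -side * float(rng.choice(VS1_MAGNITUDES))
    steady_dur = float(rng.uniform(*STEADY_DUR_RANGE_MS))
    # resample second steps whose trajectory would leave the screen too early
    # (off-screen step combinations are omitted from the design)
    for _ in range(10_000):
        ps2, vs2 = draw_second_step(rng, discrete_ps=discrete_ps)
        spec = StepRampSpec(
            fixation_x=fixation_x, ps1=ps1, vs1=vs1, steady_dur=steady_dur,
            ps2=ps2, vs2=vs2, blur=blur, trial_id=trial_id, block=block,
            session=session,
        )
        try:
            build_trial(spec)
        except ValueError:
            continue
        return spec
    raise RuntimeError("could not draw an on-screen second step-ramp")


def build_trial(
    spec: StepRampSpec,
    sample_rate: float = 1000.0,
    pre_step1_dur: float = 200.0,
    post_step2_dur: float = 1200.0,
    min_post_step2_dur: float = 800.0,
) -> TargetTrajectory:
    """Build the piecewise-linear target trajectory of one trial.

    Fixation at ``fixation_x`` for ``pre_step1_dur`` ms; at step1 the target
    jumps by ps1 and ramps at vs1; after ``steady_dur`` ms it jumps by ps2 and
    ramps at vs2 for up to ``post_step2_dur`` ms.  A fast second ramp may
    reach the screen edge before that: the trial then ends at the last
    on-screen sample (as a session would), provided at least
    ``min_post_step2_dur`` ms after step2 remain on screen — enough for the
    400-ms classification window plus late saccades.  Raises otherwise
    (callers resample such step combinations, mirroring the omission of
    off-screen steps from the design).
    """
    h = 1000.0 / sample_rate
    total = pre_step1_dur + spec.steady_dur + post_step2_dur
    n = int(round(total / h)) + 1
    t = np.arange(n) * h
    step1 = pre_step1_dur
    step2 = pre_step1_dur + spec.steady_dur
    x = np.empty(n)
    pre = t < step1
    x[pre] = spec.fixation_x
    seg1 = (t >= step1) & (t < step2)
    x[seg1] = spec.fixation_x + spec.ps1 + spec.vs1 * (t[seg1] - step1) / 1000.0
    x_at_step2 = spec.fixation_x + spec.ps1 + spec.vs1 * (step2 - step1) / 1000.0
    seg2 = t >= step2
    v2_abs = spec.vs1 + spec.vs2  # vs2 is a velocity *step* on the running ramp
    x[seg2] = x_at_step2 + spec.ps2 + v2_abs * (t[seg2] - step2) / 1000.0
    off = np.abs(x) > SCREEN_HALF_WIDTH_DEG
    if off.any():
        exit_i = int(np.argmax(off))
        if t[exit_i] < step2 + min_post_step2_dur:
            raise ValueError("target trajectory exits the +-30 deg screen bound")
        t, x = t[:exit_i], x[:exit_i]
    return TargetTrajectory(
        t=t, x=x,
        event_times={"trial_start": 0.0, "step1": step1, "step2": step2},
        spec=spec,
    )


def build_session_schedule(
    participant_id: int,
    rng: np.random.Generator | None = None,
    n_sessions: int = 10,
    blocks_per_session: int = 10,
    trials_per_block: int = 50,
    start_blurred: bool | None = None,
) -> SessionSchedule:
    """Alternating clear/blur session schedule for one participant.

    Defaults give 10 sessions x 10 blocks x 50 trials = 5000 trials.  Half of
    the participants start with the blurred condition (even participant_id
    when ``start_blurred`` is not forced).
    """
    if min(n_sessions, blocks_per_session, trials_per_block) <= 0:
        raise ValueError("session, block and trial counts must be positive")
    if start_blurred is None:
        start_blurred = participant_id % 2 == 0
    sessions = []
    for s in range(n_sessions):
        blurred = (s % 2 == 0) == start_blurred
        sessions.append(("blur" if blurred else "clear", blocks_per_session, trials_per_block))
    return SessionSchedule(
        participant_id=participant_id,
        sessions=tuple(sessions),
        counterbalance_start=start_blurred,
    )


def schedule_trial_specs(
    schedule: SessionSchedule,
    rng: np.random.Generator,
    discrete_ps: bool = False,
) -> list[StepRampSpec]:
    """Draw the full ordered list of trial specs for a schedule."""
    specs = []
    tid = 0
    for s_idx, (cond, n_blocks, n_trials) in enumerate(schedule.sessions):
        for b in range(n_blocks):
            for _ in range(n_trials):
                specs.append(
                    draw_trial_spec(
                        rng, blur=(cond == "blur"), trial_id=tid,
                        block=b, session=s_idx, discrete_ps=discrete_ps,
                    )
                )
                tid += 1
    return specs


def specs_to_json(specs: Sequence[StepRampSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh)


def specs_from_json(path) -> list[StepRampSpec]:
    with open(path) as fh:
        return [StepRampSpec(**d) for d in json.load(fh)]
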