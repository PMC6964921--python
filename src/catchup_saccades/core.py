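"""Shared containers for eye traces and saccade events."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import StepRampSpec


@dataclass
class SaccadeEvent:
    """One saccade, detected or ground truth.

    onset/offset in ms from trial start; amplitude = eye displacement over
    the event (deg, signed).
    """

    onset: float
    offset: float
    amplitude: float
    index_after_step2: int = -1  # ordinal among post-step2 saccades, -1 if before

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("saccade offset must follow onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EyeTrace:
    """Target and eye position on a uniform 1000-Hz grid plus trial metadata."""

    time: np.ndarray  # ms
    target_x: np.ndarray  # deg
    eye_x: np.ndarray  # deg
    condition: str = "clear"  # clear | blur
    step2_time: float = 0.0  # ms
    spec: StepRampSpec | None = None
    trial_id: int = 0
    participant_id: int = 0

    @property
    def sample_rate(self) -> float:
        return 1000.0 / (self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time, "target_x_deg": self.target_x, "eye_x_deg": self.eye_x}
        )


@dataclass
class DecisionTrace:
    """Per-sample internal variables of the trigger model, for inspection."""

    time: np.ndarray
    pe_est: np.ndarray
    rs_est: np.ndarray
    pe_pred_mean: np.ndarray
    pe_pred_var: np.ndarray
    evidence: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time,
                "pe_est": self.pe_est,
                "rs_est": self.rs_est,
                "pe_pred_mean": self.pe_pred_mean,
                "pe_pred_var": self.pe_pred_var,
                "evidence": self.evidence,
            }
        )
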