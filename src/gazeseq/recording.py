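"""Core containers: trial timeline and raw gaze-sample recordings."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialTimeline", "GazeRecording"]


@dataclass(frozen=True)
class TrialTimeline:
    """Trial epoch structure: fixation cross, stimulus, closing fixation cross.

    The cross is placed outside the stimulus area to prevent central fixation
    bias; ``stimulus_duration`` is the nominal presentation time (the simulator
    treats it as metadata and lets the stimulus epoch run until the planned
    visit sequence completes).
    """

    cross_duration: float = 400.0
    stimulus_duration: float = 450.0
    post_cross_duration: float = 400.0
    cross_position: tuple[float, float] = (960.0, 80.0)

    def __post_init__(self) -> None:
        for name in ("cross_duration", "stimulus_duration", "post_cross_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")


@dataclass(eq=False)
class GazeRecording:
    """Timestamped gaze-sample stream for one trial.

    ``time_ms`` is relative to trial start and strictly increasing;
    ``stimulus_onset`` marks where the stimulus epoch begins (end of the
    leading fixation cross).
    """

    participant: int
    trial: int
    condition: str
    sampling_rate: float
    time_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    stimulus_onset: float = 0.0
    timeline: TrialTimeline | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time_ms.size
        if not (self.x_px.size == self.y_px.size == self.valid.size == n):
            raise ValueError("time_ms, x_px, y_px and valid must have equal length")
        if n == 0:
            raise ValueError("recording has no samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dts = np.diff(self.time_ms)
        if np.any(dts <= 0):
            idx = int(np.argmax(dts <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at row {idx}")
        if n > 1:
            nominal = 1000.0 / self.sampling_rate
            med = float(np.median(dts))
            if not 0.8 * nominal <= med <= 1.2 * nominal:
                warnings.warn(
                    f"median inter-sample interval {med:.2f} ms deviates >20% from "
                    f"nominal {nominal:.2f} ms",
                    stacklevel=2,
                )
        bad = self.valid & ~(np.isfinite(self.x_px) & np.isfinite(self.y_px))
        if np.any(bad):
            raise ValueError("valid samples must have finite coordinates")

    @property
    def n_samples(self) -> int:
        return int(self.time_ms.size)

    @property
    def duration(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0])

    @property
    def dt(self) -> float:
        """Nominal sample period in ms."""
        return 1000.0 / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "trial": self.trial,
                "condition": self.condition,
                "time_ms": self.time_ms,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "valid": self.valid.astype(int),
            }
        )
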