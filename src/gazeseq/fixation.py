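"""Velocity-threshold (I-VT) fixation detection with a dispersion gate.

Candidate fixations are maximal runs of samples whose smoothed angular
velocity stays below ``velocity_threshold`` (default 30 deg/s). A candidate is
kept iff it lasts at least ``min_duration`` (default 100 ms) and its spatial
dispersion — the Salvucci–Goldberg measure (max x − min x) + (max y − min y),
converted to degrees — does not exceed ``dispersion_threshold`` (default
1.5 deg).

Velocity is estimated by centred neighbour differences (one-sided at the
stream ends) followed by a centred moving average (default 3 samples).
Invalid-sample gaps of at most ``max_gap_samples`` are linearly interpolated;
longer gaps break candidate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry
from .recording import GazeRecording

__all__ = ["FixationParams", "Fixation", "compute_velocity", "detect_fixations"]


@dataclass(frozen=True)
class FixationParams:
    velocity_threshold: float = 30.0  # deg/s
    dispersion_threshold: float = 1.5  # deg
    min_duration: float = 100.0  # ms
    velocity_smoothing_window: int = 3  # samples, centred
    max_gap_samples: int = 2  # invalid gaps longer than this break runs

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.dispersion_threshold, self.min_duration) <= 0:
            raise ValueError("velocity, dispersion and duration thresholds must be positive")
        if self.velocity_smoothing_window < 1:
            raise ValueError("velocity_smoothing_window must be >= 1")


@dataclass(frozen=True)
class Fixation:
    """A stable-gaze event: time bounds, centroid, and spatial dispersion."""

    start: float  # ms
    end: float  # ms
    duration: float  # ms, = end - start
    centroid_x: float
    centroid_y: float
    dispersion: float  # deg
    n_samples: int


def _interpolate_gaps(rec: GazeRecording, max_gap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill short invalid gaps by linear interpolation; flag long ones unusable."""
    x = rec.x_px.copy()
    y = rec.y_px.copy()
    ok = rec.valid.copy()
    if ok.all():
        return x, y, ok
    idx = np.arange(ok.size)
    if ok.sum() >= 2:
        x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
        y[~ok] = np.interp(idx[~ok], idx[ok], y[ok])
    usable = ok.copy()
    # short interior gaps become usable after interpolation
    i = 0
    while i < ok.size:
        if not ok[i]:
            j = i
            while j < ok.size and not ok[j]:
                j += 1
            interior = i > 0 and j < ok.size
            if interior and (j - i) <= max_gap:
                usable[i:j] = True
            i = j
        else:
            i += 1
    return x, y, usable


def compute_velocity(
    recording: GazeRecording,
    geometry: DisplayGeometry,
    smoothing: int = 3,
    max_gap_samples: int = 2,
) -> np.ndarray:
    """Per-sample angular velocity in deg/s; NaN where the stream has gaps."""
    if recording.valid.sum() == 0:
        raise ValueError("all samples invalid; cannot compute velocity")
    if recording.n_samples < 2 or recording.valid.sum() < 2:
        raise ValueError("need at least 2 valid samples to compute velocity")
    x, y, usable = _interpolate_gaps(recording, max_gap_samples)
    t = recording.time_ms
    n = t.size
    v = np.full(n, np.nan)
    # centred differences at interior samples, one-sided at the ends
    dx = x[2:] - x[:-2]
    dy = y[2:] - y[:-2]
    dt_s = (t[2:] - t[:-2]) / 1000.0
    v[1:-1] = geometry.px_to_degrees(dx, dy) / dt_s
    v[0] = geometry.px_to_degrees(x[1] - x[0], y[1] - y[0]) / ((t[1] - t[0]) / 1000.0)
    v[-1] = geometry.px_to_degrees(x[-1] - x[-2], y[-1] - y[-2]) / ((t[-1] - t[-2]) / 1000.0)
    v[~usable] = np.nan
    if smoothing > 1:
        sm = (
            pd.Series(v)
            .rolling(window=smoothing, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        sm[~usable] = np.nan
        v = sm
    return v


def detect_fixations(
    recording: GazeRecording,
    params: FixationParams = FixationParams(),
    geometry: DisplayGeometry = DisplayGeometry(),
) -> list[Fixation]:
    """I-VT detection: velocity-defined candidate runs gated by duration and dispersion."""
    x, y, usable = _interpolate_gaps(recording, params.max_gap_samples)
    v = compute_velocity(
        recording,
        geometry,
        params.velocity_smoothing_window,
        params.max_gap_samples,
    )
    below = np.zeros(recording.n_samples, dtype=bool)
    finite = np.isfinite(v)
    below[finite] = v[finite] < params.velocity_threshold
    below &= usable
    t = recording.time_ms

    fixations: list[Fixation] = []
    n = below.size
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        duration = t[j] - t[i]
        if duration >= params.min_duration:
            xs = x[i : j + 1]
            ys = y[i : j + 1]
            dispersion = geometry.px_to_degrees(
                float(xs.max() - xs.min()), 0.0
            ) + geometry.px_to_degrees(0.0, float(ys.max() - ys.min()))
            if dispersion <= params.dispersion_threshold:
                fixations.append(
                    Fixation(
                        start=float(t[i]),
                        end=float(t[j]),
                        duration=float(duration),
                        centroid_x=float(xs.mean()),
                        centroid_y=float(ys.mean()),
                        dispersion=float(dispersion),
                        n_samples=j - i + 1,
                    )
                )
        i = j + 1
    return fixations
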