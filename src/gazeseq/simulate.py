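"""Synthetic gaze-sample generator with a controllable attention model.

The generator emulates a brief-exposure A/B eye-tracking trial: a fixation
cross shown outside the stimulus area, the stimulus, then a closing cross,
sampled at 120 Hz. Gaze behaviour during the stimulus is driven by an
adherence-mixture model: the trial plans one visit slot per symbol of the
intended AOI sequence, and each slot targets the next intended AOI with
probability ``adherence``, otherwise a uniformly random AOI. Planned visits
are fixations (Gaussian duration, ornstein-uhlenbeck fixational drift plus
white measurement noise) joined by constant-velocity saccades.

Saccade duration defaults to amplitude-scaled (one sample interval per degree
of amplitude, minimum two intervals), which keeps saccadic velocity in the
60–120 deg/s band: unambiguously above the 30 deg/s detection threshold yet
slow enough that velocity smoothing cannot smear a saccade across more than
one boundary sample. Ground truth (planned visit labels and fixation
intervals on the sample grid) is returned alongside every recording.

All randomness flows through numpy Generators; a fixed seed reproduces
recordings bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .aoi import AOISet
from .design import ExperimentDesign
from .geometry import DisplayGeometry
from .recording import GazeRecording, TrialTimeline

__all__ = [
    "AttentionModel",
    "StimulusMeta",
    "GroundTruthFixation",
    "TrialGroundTruth",
    "ExperimentResult",
    "simulate_trial",
    "simulate_experiment",
]

# amplitude (deg) covered per sample interval during a saccade when
# saccade_duration is amplitude-scaled
_SACCADE_STEP_DEG = 1.0
# fixational drift correlation time (ms); slow drift, as in real fixations
_JITTER_TAU_MS = 300.0


@dataclass(frozen=True)
class AttentionModel:
    """Generative parameters for one condition's gaze behaviour.

    adherence          probability each planned visit follows the intended
                       order rather than jumping to a uniformly random AOI
    fixation_duration_mean/sd/min
                       planned fixation durations (ms), normal, clipped at min
    saccade_duration   fixed saccade duration in ms, or None for
                       amplitude-scaled (recommended)
    jitter_sd          fixational drift amplitude, deg (stationary SD of an
                       OU process with a 300 ms time constant)
    measurement_noise_sd
                       white tracker noise per sample, px
    """

    intended_sequence: str = ""
    adherence: float = 0.8
    fixation_duration_mean: float = 180.0
    fixation_duration_sd: float = 30.0
    fixation_duration_min: float = 130.0
    saccade_duration: float | None = None
    jitter_sd: float = 0.15
    measurement_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError(f"adherence must be in [0, 1], got {self.adherence}")
        if self.fixation_duration_mean < 100.0:
            raise ValueError(
                "fixation_duration_mean must be >= 100 ms so planned visits are "
                f"detectable, got {self.fixation_duration_mean}"
            )
        if self.fixation_duration_sd < 0 or self.jitter_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.saccade_duration is not None and self.saccade_duration <= 0:
            raise ValueError("saccade_duration must be positive when given")


@dataclass(frozen=True)
class StimulusMeta:
    """A stimulus: its AOI set plus optional salience / colour metadata."""

    stimulus_id: str
    aois: AOISet
    salience: Mapping[str, float] | None = None
    color_metadata: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.salience is not None:
            bad = {k: v for k, v in self.salience.items() if v < 0}
            if bad:
                raise ValueError(f"salience weights must be >= 0, got {bad}")


@dataclass(frozen=True)
class GroundTruthFixation:
    """One planned stable-gaze interval on the sample grid; label None = cross."""

    label: str | None
    start: float
    end: float


@dataclass(frozen=True)
class TrialGroundTruth:
    participant: int
    trial: int
    condition: str
    visits: tuple[str, ...]  # planned visit labels, uncollapsed
    fixations: tuple[GroundTruthFixation, ...]  # incl. cross fixations


def _resolve_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_trial(
    timeline: TrialTimeline,
    model: AttentionModel,
    stimulus: StimulusMeta,
    geometry: DisplayGeometry = DisplayGeometry(),
    rate: float = 120.0,
    seed=0,
    participant: int = 0,
    trial: int = 0,
    condition: str = "",
) -> tuple[GazeRecording, TrialGroundTruth]:
    """Simulate one trial; returns the recording and its ground truth."""
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    aois = stimulus.aois
    if not aois.aois:
        raise ValueError("stimulus has no AOIs")
    intended = model.intended_sequence or aois.intended_sequence
    unknown = sorted({c for c in intended if c not in aois.labels})
    if unknown:
        raise ValueError(
            f"intended_sequence references unknown AOI label(s) {unknown}; "
            f"stimulus {stimulus.stimulus_id!r} defines {list(aois.labels)}"
        )
    cx, cy = timeline.cross_position
    for a in aois.aois:
        if a.contains(cx, cy):
            raise ValueError(
                f"cross_position {timeline.cross_position} lies inside AOI {a.label!r}"
            )

    rng = _resolve_rng(seed)
    dt = 1000.0 / rate
    labels = list(aois.labels)
    centroids = {a.label: a.centroid for a in aois.aois}

    # --- plan visit targets (adherence mixture) and durations -------------
    targets: list[str] = []
    for ch in intended:
        if rng.random() < model.adherence:
            targets.append(ch)
        else:
            targets.append(labels[int(rng.integers(len(labels)))])
    durations = np.clip(
        rng.normal(model.fixation_duration_mean, model.fixation_duration_sd, len(targets)),
        model.fixation_duration_min,
        None,
    )
    # merge consecutive same-AOI visits into one planned fixation
    merged: list[tuple[str, float]] = []
    for label, dur in zip(targets, durations):
        if merged and merged[-1][0] == label:
            merged[-1] = (label, merged[-1][1] + dur)
        else:
            merged.append((label, float(dur)))

    # --- lay out the continuous gaze path ---------------------------------
    knots_t: list[float] = []
    knots_x: list[float] = []
    knots_y: list[float] = []
    events: list[tuple[str | None, float, float]] = []
    t = 0.0

    def add_fixation(pos: tuple[float, float], dur: float, label: str | None) -> None:
        nonlocal t
        knots_t.extend([t, t + dur])
        knots_x.extend([pos[0], pos[0]])
        knots_y.extend([pos[1], pos[1]])
        events.append((label, t, t + dur))
        t += dur

    def add_saccade(p: tuple[float, float], q: tuple[float, float]) -> None:
        nonlocal t
        amplitude = geometry.px_to_degrees(q[0] - p[0], q[1] - p[1])
        if model.saccade_duration is not None:
            dur = model.saccade_duration
        else:
            n_intervals = max(2, math.ceil(amplitude / _SACCADE_STEP_DEG))
            dur = n_intervals * dt
        knots_t.extend([t, t + dur])
        knots_x.extend([p[0], q[0]])
        knots_y.extend([p[1], q[1]])
        t += dur

    cross = (float(cx), float(cy))
    add_fixation(cross, timeline.cross_duration, None)
    pos = cross
    for label, dur in merged:
        target = centroids[label]
        add_saccade(pos, target)
        add_fixation(target, dur, label)
        pos = target
    add_saccade(pos, cross)
    add_fixation(cross, timeline.post_cross_duration, None)

    # --- sample on the grid and add noise ----------------------------------
    n = int(math.floor(t / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    x = np.interp(times, knots_t, knots_x)
    y = np.interp(times, knots_t, knots_y)

    if model.jitter_sd > 0:
        sd_px = np.array(
            [geometry.degrees_to_px(model.jitter_sd, "x"), geometry.degrees_to_px(model.jitter_sd, "y")]
        )
        a = math.exp(-dt / _JITTER_TAU_MS)
        innovations = rng.standard_normal((2, n)) * (sd_px * math.sqrt(1 - a * a))[:, None]
        start = rng.standard_normal(2) * sd_px
        drift = lfilter([1.0], [1.0, -a], innovations, axis=-1)
        drift += start[:, None] * a ** np.arange(1, n + 1)
        x = x + drift[0]
        y = y + drift[1]
    if model.measurement_noise_sd > 0:
        x = x + rng.normal(0.0, model.measurement_noise_sd, n)
        y = y + rng.normal(0.0, model.measurement_noise_sd, n)

    recording = GazeRecording(
        participant=participant,
        trial=trial,
        condition=condition,
        sampling_rate=rate,
        time_ms=times,
        x_px=x,
        y_px=y,
        valid=np.ones(n, dtype=bool),
        stimulus_onset=timeline.cross_duration,
        timeline=timeline,
    )
    gt_fix = []
    for label, t_on, t_off in events:
        first = math.ceil(t_on / dt - 1e-9)
        last = min(math.floor(t_off / dt + 1e-9), n - 1)
        gt_fix.append(GroundTruthFixation(label=label, start=first * dt, end=last * dt))
    ground_truth = TrialGroundTruth(
        participant=participant,
        trial=trial,
        condition=condition,
        visits=tuple(targets),
        fixations=tuple(gt_fix),
    )
    return recording, ground_truth


@dataclass
class ExperimentResult:
    """All recordings and ground truth of one simulated experiment."""

    design: ExperimentDesign
    recordings: list[GazeRecording]
    ground_truths: list[TrialGroundTruth]
    orders: np.ndarray  # (n_participants, n_trials) condition indices

    def ground_truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [g.participant for g in self.ground_truths],
                "trial": [g.trial for g in self.ground_truths],
                "condition": [g.condition for g in self.ground_truths],
                "true_visits": ["".join(g.visits) for g in self.ground_truths],
            }
        )


def simulate_experiment(
    design: ExperimentDesign,
    models: Mapping[str, AttentionModel],
    stimuli: Mapping[str, StimulusMeta],
    geometry: DisplayGeometry = DisplayGeometry(),
    timeline: TrialTimeline = TrialTimeline(),
) -> ExperimentResult:
    """Simulate the full participants x trials design.

    Per-trial seeds derive deterministically from (design.seed, participant,
    trial), so the experiment is reproducible and any trial can be
    regenerated in isolation.
    """
    for cond in design.conditions:
        if cond not in models:
            raise ValueError(f"no AttentionModel for condition {cond!r}")
        if cond not in stimuli:
            raise ValueError(f"no StimulusMeta for condition {cond!r}")
    orders = design.participant_orders()
    recordings: list[GazeRecording] = []
    ground_truths: list[TrialGroundTruth] = []
    for p in range(design.n_participants):
        for tr in range(design.n_trials):
            cond = design.conditions[int(orders[p, tr])]
            seed = np.random.SeedSequence((design.seed, p, tr))
            rec, gt = simulate_trial(
                timeline,
                models[cond],
                stimuli[cond],
                geometry,
                rate=design.sampling_rate,
                seed=seed,
                participant=p,
                trial=tr,
                condition=cond,
            )
            recordings.append(rec)
            ground_truths.append(gt)
    return ExperimentResult(
        design=design, recordings=recordings, ground_truths=ground_truths, orders=orders
    )
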