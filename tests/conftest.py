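"""Shared fixtures: geometry, a small AOI set, and synthetic recordings."""

import numpy as np
import pytest

from gazeseq import (
    AOI,
    AOISet,
    AttentionModel,
    DisplayGeometry,
    GazeRecording,
    StimulusMeta,
    TrialTimeline,
)

DT_MS = 1000.0 / 120.0


@pytest.fixture(scope="session")
def geometry() -> DisplayGeometry:
    return DisplayGeometry()


@pytest.fixture(scope="session")
def abc_aois() -> AOISet:
    """Three 200 px square AOIs in a row, intended order A -> B -> C."""
    return AOISet(
        stimulus="abc",
        aois=(
            AOI(label="A", rect=(460.0, 440.0, 200.0, 200.0)),
            AOI(label="B", rect=(860.0, 440.0, 200.0, 200.0)),
            AOI(label="C", rect=(1260.0, 440.0, 200.0, 200.0)),
        ),
        intended_sequence="ABC",
    )


@pytest.fixture(scope="session")
def abc_stimulus(abc_aois) -> StimulusMeta:
    return StimulusMeta(stimulus_id="abc", aois=abc_aois)


@pytest.fixture(scope="session")
def timeline() -> TrialTimeline:
    return TrialTimeline()


@pytest.fixture
def noiseless_model() -> AttentionModel:
    return AttentionModel(adherence=1.0, jitter_sd=0.0, measurement_noise_sd=0.0)


def make_recording(x, y, rate=120.0, valid=None, **kwargs) -> GazeRecording:
    """Recording from coordinate arrays on a regular 120 Hz grid."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeRecording(
        participant=kwargs.pop("participant", 0),
        trial=kwargs.pop("trial", 0),
        condition=kwargs.pop("condition", ""),
        sampling_rate=rate,
        time_ms=np.arange(n) * (1000.0 / rate),
        x_px=x,
        y_px=np.asarray(y, dtype=float),
        valid=np.asarray(valid, dtype=bool),
        **kwargs,
    )


@pytest.fixture(scope="session")
def stationary_recording() -> GazeRecording:
    n = 60
    return make_recording(np.full(n, 800.0), np.full(n, 500.0))
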