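"""Default study configuration: an 8-condition A/B brief-exposure design.

Four visual-guidance strategies, each with a treatment and a control variant,
on a 1920 x 1080 display:

* colour brightness — three symbols (A yellow, B red, C green) in a row;
  hypothesised visit order A→B→C. Bright vs dull (30% brightness) variants
  share the AOI layout; approximate luminances are carried as metadata only.
* layering — a foreground symbol at the bottom (A) and background symbol at
  the top (B); hypothesised bottom-to-top order A→B.
* line guidance — six symbols left to right (A–F), connected by a line in the
  treatment variant; hypothesised left-to-right order.
* size variation — five symbols left to right (A–E), graded large-to-small in
  the treatment variant; hypothesised left-to-right order.

Adherence defaults encode the directional hypotheses: treatments that are
expected to guide gaze get higher adherence than their controls, and the size
manipulation (reported as weakly effective in this class of designs) gets a
near-null contrast. These values are a stated world for testing the pipeline,
not estimates from any dataset.
"""

from __future__ import annotations

from .aoi import AOI, AOISet
from .design import DEFAULT_CONDITIONS, ExperimentDesign
from .geometry import DisplayGeometry
from .recording import TrialTimeline
from .simulate import AttentionModel, StimulusMeta

__all__ = [
    "default_geometry",
    "default_timeline",
    "default_aoi_sets",
    "default_models",
    "default_design",
    "default_study",
]

_ADHERENCE = {
    "color_bright": 0.85,
    "color_dull": 0.60,
    "layered": 0.85,
    "non_layered": 0.60,
    "line_connected": 0.85,
    "line_plain": 0.60,
    "size_graded": 0.65,
    "size_equal": 0.60,
}

_COLOR_META = {
    "bright_luminance_cd_m2": {"A": 230.0, "B": 78.0, "C": 145.0},
    "dull_brightness_fraction": 0.30,
}


def default_geometry() -> DisplayGeometry:
    return DisplayGeometry()


def default_timeline() -> TrialTimeline:
    return TrialTimeline(cross_duration=400.0, stimulus_duration=450.0,
                         post_cross_duration=400.0, cross_position=(960.0, 80.0))


def _row(labels: str, centers_x: list[float], center_y: float, size: float) -> list[AOI]:
    half = size / 2.0
    return [
        AOI(label=lab, rect=(cx - half, center_y - half, size, size))
        for lab, cx in zip(labels, centers_x)
    ]


def default_aoi_sets() -> dict[str, AOISet]:
    """Per-condition AOI sets; A/B variants of a strategy share the layout."""
    color = AOISet(
        stimulus="color",
        aois=tuple(_row("ABC", [560.0, 960.0, 1360.0], 540.0, 220.0)),
        intended_sequence="ABC",
    )
    layer = AOISet(
        stimulus="layer",
        aois=(
            AOI(label="A", rect=(850.0, 690.0, 220.0, 220.0)),  # bottom, foreground
            AOI(label="B", rect=(850.0, 190.0, 220.0, 220.0)),  # top, background
        ),
        intended_sequence="AB",
    )
    line = AOISet(
        stimulus="line",
        aois=tuple(_row("ABCDEF", [260.0, 540.0, 820.0, 1100.0, 1380.0, 1660.0], 540.0, 180.0)),
        intended_sequence="ABCDEF",
    )
    size = AOISet(
        stimulus="size",
        aois=tuple(_row("ABCDE", [360.0, 660.0, 960.0, 1260.0, 1560.0], 540.0, 200.0)),
        intended_sequence="ABCDE",
    )
    return {
        "color_bright": color,
        "color_dull": color,
        "layered": layer,
        "non_layered": layer,
        "line_connected": line,
        "line_plain": line,
        "size_graded": size,
        "size_equal": size,
    }


def default_models() -> dict[str, AttentionModel]:
    return {cond: AttentionModel(adherence=_ADHERENCE[cond]) for cond in DEFAULT_CONDITIONS}


def default_stimuli() -> dict[str, StimulusMeta]:
    aoi_sets = default_aoi_sets()
    stimuli = {}
    for cond in DEFAULT_CONDITIONS:
        meta = _COLOR_META if cond.startswith("color") else None
        stimuli[cond] = StimulusMeta(stimulus_id=cond, aois=aoi_sets[cond], color_metadata=meta)
    return stimuli


def default_design(n_participants: int = 34, seed: int = 0) -> ExperimentDesign:
    return ExperimentDesign(n_participants=n_participants, seed=seed)


def default_study(n_participants: int = 34, seed: int = 0):
    """(design, models, stimuli, geometry, timeline) for the default experiment."""
    return (
        default_design(n_participants=n_participants, seed=seed),
        default_models(),
        default_stimuli(),
        default_geometry(),
        default_timeline(),
    )
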