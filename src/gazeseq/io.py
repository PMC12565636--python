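"""CSV/JSON/YAML readers and writers for every pipeline stage.

Interchange formats are deliberately plain: gaze samples, fixations, metrics
and stats as CSV; AOI sets and ground truth as JSON (YAML accepted for
configuration). An "smi" dialect maps SMI-style exported column names
(Time, L POR X [px], ...) onto the native sample schema.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .aoi import AOI, AOISet
from .fixation import Fixation
from .recording import GazeRecording
from .simulate import GroundTruthFixation, TrialGroundTruth

__all__ = [
    "SAMPLE_COLUMNS",
    "write_samples",
    "read_samples",
    "fixations_frame",
    "write_fixations",
    "read_fixations",
    "fixations_from_frame",
    "aoi_set_to_dict",
    "aoi_set_from_dict",
    "save_aoi_sets",
    "load_aoi_sets",
    "write_ground_truth",
    "read_ground_truth",
    "load_config",
]

SAMPLE_COLUMNS = ["participant", "trial", "condition", "time_ms", "x_px", "y_px", "valid"]

_SMI_ALIASES = {
    "Time": "time_ms",
    "L POR X [px]": "x_px",
    "L POR Y [px]": "y_px",
    "L POR X": "x_px",
    "L POR Y": "y_px",
    "Participant": "participant",
    "Trial": "trial",
    "Stimulus": "condition",
    "Condition": "condition",
    "Validity": "valid",
}


# --------------------------------------------------------------------------
# gaze samples
# --------------------------------------------------------------------------

def write_samples(recordings: Iterable[GazeRecording], path) -> None:
    frame = pd.concat([r.to_frame() for r in recordings], ignore_index=True)
    frame.to_csv(path, index=False)


def read_samples(
    path,
    dialect: str = "native",
    sampling_rate: float | None = None,
    stimulus_onset: float = 0.0,
) -> list[GazeRecording]:
    """Read a samples CSV into recordings grouped by participant x trial.

    Timestamps are normalised to trial-relative ms. ``dialect`` is "native"
    or "smi" (column aliases). ``stimulus_onset`` is not stored in the CSV
    and must be supplied by the caller (it comes from the trial timeline).
    """
    if dialect not in ("native", "smi"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path)
    if dialect == "smi":
        frame = frame.rename(columns=_SMI_ALIASES)
    required = ["participant", "trial", "time_ms", "x_px", "y_px"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"samples file {path} is missing column(s) {missing}")
    if "condition" not in frame.columns:
        frame["condition"] = ""
    if "valid" not in frame.columns:
        frame["valid"] = 1
    recordings = []
    for (participant, trial), grp in frame.groupby(["participant", "trial"], sort=True):
        t = grp["time_ms"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1])
            raise ValueError(
                f"non-monotone timestamps for participant {participant} trial "
                f"{trial} at file row {row}"
            )
        t = t - t[0]
        rate = sampling_rate
        if rate is None:
            med = float(np.median(np.diff(t))) if t.size > 1 else 1.0
            rate = 1000.0 / med
        recordings.append(
            GazeRecording(
                participant=int(participant),
                trial=int(trial),
                condition=str(grp["condition"].iloc[0]),
                sampling_rate=rate,
                time_ms=t,
                x_px=grp["x_px"].to_numpy(dtype=float),
                y_px=grp["y_px"].to_numpy(dtype=float),
                valid=grp["valid"].to_numpy().astype(bool),
                stimulus_onset=stimulus_onset,
            )
        )
    return recordings


# --------------------------------------------------------------------------
# fixations
# --------------------------------------------------------------------------

def fixations_frame(
    per_trial: Iterable[tuple[GazeRecording, Sequence[Fixation]]],
) -> pd.DataFrame:
    rows = []
    for rec, fixations in per_trial:
        for f in fixations:
            rows.append(
                {
                    "participant": rec.participant,
                    "trial": rec.trial,
                    "condition": rec.condition,
                    "start_ms": f.start,
                    "end_ms": f.end,
                    "duration_ms": f.duration,
                    "x_px": f.centroid_x,
                    "y_px": f.centroid_y,
                    "dispersion_deg": f.dispersion,
                    "n_samples": f.n_samples,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "trial",
            "condition",
            "start_ms",
            "end_ms",
            "duration_ms",
            "x_px",
            "y_px",
            "dispersion_deg",
            "n_samples",
        ],
    )


def write_fixations(per_trial, path) -> None:
    fixations_frame(per_trial).to_csv(path, index=False)


def read_fixations(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("participant", "trial", "start_ms", "duration_ms") if c not in frame.columns]
    if missing:
        raise ValueError(f"fixations file {path} is missing column(s) {missing}")
    return frame


def fixations_from_frame(frame: pd.DataFrame) -> list[Fixation]:
    """Rebuild Fixation objects from rows of a fixations table (one trial)."""
    out = []
    for _, r in frame.sort_values("start_ms").iterrows():
        end = r["end_ms"] if "end_ms" in r else r["start_ms"] + r["duration_ms"]
        out.append(
            Fixation(
                start=float(r["start_ms"]),
                end=float(end),
                duration=float(r["duration_ms"]),
                centroid_x=float(r["x_px"]),
                centroid_y=float(r["y_px"]),
                dispersion=float(r.get("dispersion_deg", 0.0)),
                n_samples=int(r.get("n_samples", 0)),
            )
        )
    return out


# --------------------------------------------------------------------------
# AOI configuration
# --------------------------------------------------------------------------

def aoi_set_to_dict(aois: AOISet) -> dict:
    entries = []
    for a in aois.aois:
        if a.rect is not None:
            entries.append({"label": a.label, "rect": list(a.rect)})
        else:
            entries.append({"label": a.label, "polygon": [list(p) for p in a.polygon]})
    return {
        "stimulus": aois.stimulus,
        "aois": entries,
        "intended_sequence": aois.intended_sequence,
    }


def aoi_set_from_dict(d: Mapping) -> AOISet:
    aois = []
    for entry in d["aois"]:
        if "rect" in entry:
            aois.append(AOI(label=entry["label"], rect=tuple(entry["rect"])))
        elif "polygon" in entry:
            aois.append(
                AOI(label=entry["label"], polygon=tuple(tuple(p) for p in entry["polygon"]))
            )
        else:
            raise ValueError(f"AOI entry {entry!r} has neither rect nor polygon")
    return AOISet(
        stimulus=d.get("stimulus", ""),
        aois=tuple(aois),
        intended_sequence=d.get("intended_sequence", ""),
    )


def save_aoi_sets(aoi_sets: Mapping[str, AOISet], path) -> None:
    payload = {cond: aoi_set_to_dict(s) for cond, s in aoi_sets.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_aoi_sets(path) -> dict[str, AOISet]:
    """Load AOI config (JSON or YAML): condition -> AOISet mapping.

    A file holding a single AOI-set object is returned under its stimulus id.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if "aois" in data:  # single set
        s = aoi_set_from_dict(data)
        return {s.stimulus: s}
    return {cond: aoi_set_from_dict(d) for cond, d in data.items()}


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def write_ground_truth(ground_truths: Iterable[TrialGroundTruth], path) -> None:
    payload = [
        {
            "participant": g.participant,
            "trial": g.trial,
            "condition": g.condition,
            "visits": "".join(g.visits),
            "fixations": [
                {"label": f.label, "start_ms": f.start, "end_ms": f.end}
                for f in g.fixations
            ],
        }
        for g in ground_truths
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> list[TrialGroundTruth]:
    data = json.loads(Path(path).read_text())
    return [
        TrialGroundTruth(
            participant=d["participant"],
            trial=d["trial"],
            condition=d["condition"],
            visits=tuple(d["visits"]),
            fixations=tuple(
                GroundTruthFixation(
                    label=f["label"], start=f["start_ms"], end=f["end_ms"]
                )
                for f in d["fixations"]
            ),
        )
        for d in data
    ]


def load_config(path) -> dict:
    """Load a pipeline configuration mapping from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)
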