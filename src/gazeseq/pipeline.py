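"""File-based pipeline stages and their end-to-end composition.

Each stage consumes and produces the plain-text interchange files defined in
:mod:`gazeseq.io`, so ``run_all`` is exactly the composition of the individual
stages. The CLI in :mod:`gazeseq.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import io as gio
from . import presets
from .design import DEFAULT_CONDITIONS, ExperimentDesign
from .fixation import FixationParams, detect_fixations
from .geometry import DisplayGeometry
from .metrics import AnalysisWindow, is_first_of_block, metrics_table, trial_metrics
from .recording import TrialTimeline
from .similarity import similarity_ratio
from .simulate import simulate_experiment
from .stats import ComparisonSpec, format_report, run_comparisons

__all__ = ["PipelineConfig", "simulate_stage", "fixation_stage", "sequence_stage",
           "metrics_stage", "stats_stage", "run_all", "default_comparisons"]


def default_comparisons() -> list[ComparisonSpec]:
    """Sequence-alignment comparisons for the four default strategy pairs."""
    pairs = [
        ("color", "color_bright", "color_dull"),
        ("layer", "layered", "non_layered"),
        ("line", "line_connected", "line_plain"),
        ("size", "size_graded", "size_equal"),
    ]
    specs = []
    for name, a, b in pairs:
        for metric in ("distance", "similarity"):
            specs.append(
                ComparisonSpec(
                    metric=metric, condition_a=a, condition_b=b,
                    name=f"{name}-{metric}",
                )
            )
    return specs


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (YAML/JSON-loadable)."""

    n_participants: int = 34
    seed: int = 0
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    timeline: TrialTimeline = field(default_factory=presets.default_timeline)
    fixation_params: FixationParams = field(default_factory=FixationParams)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    collapse: bool = True
    exclude_first_trials: bool = False
    block_size: int = 4
    comparisons: list[ComparisonSpec] = field(default_factory=default_comparisons)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "n_participants" in d:
            cfg.n_participants = int(d["n_participants"])
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "geometry" in d:
            cfg.geometry = DisplayGeometry(**d["geometry"])
        if "timeline" in d:
            t = dict(d["timeline"])
            if "cross_position" in t:
                t["cross_position"] = tuple(t["cross_position"])
            cfg.timeline = TrialTimeline(**t)
        if "fixation_params" in d:
            cfg.fixation_params = FixationParams(**d["fixation_params"])
        if "window" in d:
            w = d["window"]
            cfg.window = AnalysisWindow(start=w.get("start", 0.0), end=w.get("end"))
        if "collapse" in d:
            cfg.collapse = bool(d["collapse"])
        if "exclude_first_trials" in d:
            cfg.exclude_first_trials = bool(d["exclude_first_trials"])
        if "block_size" in d:
            cfg.block_size = int(d["block_size"])
        if "comparisons" in d:
            cfg.comparisons = [ComparisonSpec(**c) for c in d["comparisons"]]
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(gio.load_config(path))


def simulate_stage(outdir, config: PipelineConfig) -> dict[str, Path]:
    """Simulate the default study; write samples, ground truth, AOIs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, models, stimuli, _, _ = presets.default_study(
        n_participants=config.n_participants, seed=config.seed
    )
    result = simulate_experiment(
        design, models, stimuli, config.geometry, config.timeline
    )
    paths = {
        "samples": outdir / "samples.csv",
        "ground_truth": outdir / "ground_truth.json",
        "aois": outdir / "aois.json",
        "manifest": outdir / "manifest.json",
    }
    gio.write_samples(result.recordings, paths["samples"])
    gio.write_ground_truth(result.ground_truths, paths["ground_truth"])
    gio.save_aoi_sets(presets.default_aoi_sets(), paths["aois"])
    manifest = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_trials": design.n_trials,
        "conditions": list(design.conditions),
        "sampling_rate": design.sampling_rate,
        "stimulus_onset": config.timeline.cross_duration,
        "adherence": {c: models[c].adherence for c in design.conditions},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def fixation_stage(samples_path, out_path, config: PipelineConfig,
                   dialect: str = "native") -> Path:
    """Detect fixations in a samples CSV; write the fixations CSV."""
    recordings = gio.read_samples(
        samples_path, dialect=dialect, stimulus_onset=config.timeline.cross_duration
    )
    per_trial = [
        (rec, detect_fixations(rec, config.fixation_params, config.geometry))
        for rec in recordings
    ]
    gio.write_fixations(per_trial, out_path)
    return Path(out_path)


def sequence_stage(fixations_path, aois_path, out_path, config: PipelineConfig) -> Path:
    """Build per-trial scanpath strings and similarity scores; write CSV."""
    frame = gio.read_fixations(fixations_path)
    aoi_sets = gio.load_aoi_sets(aois_path)
    onset = config.timeline.cross_duration
    rows = []
    for (participant, trial, condition), grp in frame.groupby(
        ["participant", "trial", "condition"], sort=True
    ):
        aois = aoi_sets[str(condition)]
        tm = trial_metrics(
            gio.fixations_from_frame(grp),
            aois,
            participant=int(participant),
            trial=int(trial),
            condition=str(condition),
            onset=onset,
            window=config.window,
            collapse=config.collapse,
        )
        rows.append(
            {
                "participant": participant,
                "trial": trial,
                "condition": condition,
                "observed_sequence": tm.observed_sequence,
                "intended_sequence": tm.intended_sequence,
                "distance": tm.similarity.distance,
                "ratio": tm.similarity.ratio,
                "ratio_percent": tm.similarity.ratio_percent,
            }
        )
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return Path(out_path)


def metrics_stage(fixations_path, aois_path, out_path, config: PipelineConfig) -> Path:
    """Per-trial AOI + sequence metrics as the tidy long table; write CSV."""
    frame = gio.read_fixations(fixations_path)
    aoi_sets = gio.load_aoi_sets(aois_path)
    onset = config.timeline.cross_duration
    trials = []
    for (participant, trial, condition), grp in frame.groupby(
        ["participant", "trial", "condition"], sort=True
    ):
        excluded = config.exclude_first_trials and is_first_of_block(
            int(trial), config.block_size
        )
        trials.append(
            trial_metrics(
                gio.fixations_from_frame(grp),
                aoi_sets[str(condition)],
                participant=int(participant),
                trial=int(trial),
                condition=str(condition),
                onset=onset,
                window=config.window,
                collapse=config.collapse,
                excluded=excluded,
            )
        )
    metrics_table(trials).to_csv(out_path, index=False)
    return Path(out_path)


def stats_stage(metrics_path, out_csv, out_report, config: PipelineConfig) -> Path:
    """Paired comparisons over a metrics CSV; write results CSV and text report."""
    table = pd.read_csv(metrics_path, keep_default_na=True)
    table["aoi"] = table["aoi"].fillna("")
    results = run_comparisons(table, config.comparisons)
    results.to_csv(out_csv, index=False)
    Path(out_report).write_text(format_report(results))
    return Path(out_csv)


def run_all(outdir, config: PipelineConfig) -> dict[str, Path]:
    """simulate -> fixations -> sequences -> metrics -> stats on one directory."""
    outdir = Path(outdir)
    paths = simulate_stage(outdir, config)
    paths["fixations"] = fixation_stage(paths["samples"], outdir / "fixations.csv", config)
    paths["sequences"] = sequence_stage(
        paths["fixations"], paths["aois"], outdir / "sequences.csv", config
    )
    paths["metrics"] = metrics_stage(
        paths["fixations"], paths["aois"], outdir / "metrics.csv", config
    )
    paths["stats"] = stats_stage(
        paths["metrics"], outdir / "stats.csv", outdir / "report.txt", config
    )
    return paths
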