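"""Per-trial AOI attention metrics: time to first fixation and dwell time.

TTFF is the latency from stimulus onset to the *start* of the first fixation
inside the AOI lasting at least 100 ms; dwell time is the summed duration of
such qualifying fixations. A fixation qualifies when it is assigned to the
AOI, lasts at least ``min_fixation_ms``, and starts inside the analysis
window. The window defaults to unbounded after onset; a fixation that starts
inside a bounded window but ends past it is counted in full, matching the
"start of fixation" convention used for TTFF. A trial with no qualifying
fixation in an AOI has a missing TTFF (never imputed) and zero dwell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aoi import AOISet, assign_fixation, scanpath_string
from .fixation import Fixation
from .similarity import SimilarityResult, similarity_ratio

__all__ = [
    "AnalysisWindow",
    "AOIMetrics",
    "TrialMetrics",
    "ttff",
    "dwell_time",
    "trial_metrics",
    "metrics_table",
    "is_first_of_block",
]

QUALIFYING_FIXATION_MS = 100.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Analysis window in ms relative to stimulus onset; end None = unbounded."""

    start: float = 0.0
    end: float | None = None

    def __post_init__(self) -> None:
        if self.end is not None and not self.start < self.end:
            raise ValueError(f"window start must precede end, got [{self.start}, {self.end})")


def _qualifying(
    fixations: Sequence[Fixation],
    aoi: str,
    aois: AOISet,
    onset: float,
    window: AnalysisWindow,
    min_fixation_ms: float,
) -> list[Fixation]:
    if aoi not in aois:
        raise KeyError(f"unknown AOI label {aoi!r}; stimulus defines {list(aois.labels)}")
    lo = onset + window.start
    hi = None if window.end is None else onset + window.end
    out = []
    for fix in fixations:
        if fix.start < lo or (hi is not None and fix.start >= hi):
            continue
        if fix.duration < min_fixation_ms:
            continue
        if assign_fixation(fix, aois) == aoi:
            out.append(fix)
    return out


def ttff(
    fixations: Sequence[Fixation],
    aoi: str,
    aois: AOISet,
    onset: float = 0.0,
    window: AnalysisWindow = AnalysisWindow(),
    min_fixation_ms: float = QUALIFYING_FIXATION_MS,
) -> float | None:
    """Latency (ms) from onset to the first qualifying fixation in the AOI, or None."""
    qual = _qualifying(fixations, aoi, aois, onset, window, min_fixation_ms)
    return qual[0].start - onset if qual else None


def dwell_time(
    fixations: Sequence[Fixation],
    aoi: str,
    aois: AOISet,
    onset: float = 0.0,
    window: AnalysisWindow = AnalysisWindow(),
    min_fixation_ms: float = QUALIFYING_FIXATION_MS,
) -> float:
    """Total duration (ms) of qualifying fixations in the AOI; 0 if none."""
    qual = _qualifying(fixations, aoi, aois, onset, window, min_fixation_ms)
    return float(sum(f.duration for f in qual))


@dataclass(frozen=True)
class AOIMetrics:
    aoi: str
    ttff: float | None
    dwell: float
    n_fixations: int


@dataclass(frozen=True)
class TrialMetrics:
    """One trial's per-AOI metrics plus its scanpath similarity result."""

    participant: int
    trial: int
    condition: str
    aoi_metrics: Mapping[str, AOIMetrics]
    observed_sequence: str
    intended_sequence: str
    similarity: SimilarityResult
    excluded: bool = False


def trial_metrics(
    fixations: Sequence[Fixation],
    aois: AOISet,
    participant: int = 0,
    trial: int = 0,
    condition: str = "",
    onset: float = 0.0,
    window: AnalysisWindow = AnalysisWindow(),
    collapse: bool = True,
    min_fixation_ms: float = QUALIFYING_FIXATION_MS,
    excluded: bool = False,
) -> TrialMetrics:
    """Join AOI metrics and scanpath similarity for one trial."""
    per_aoi = {}
    for label in aois.labels:
        qual = _qualifying(fixations, label, aois, onset, window, min_fixation_ms)
        per_aoi[label] = AOIMetrics(
            aoi=label,
            ttff=qual[0].start - onset if qual else None,
            dwell=float(sum(f.duration for f in qual)),
            n_fixations=len(qual),
        )
    win = (window.start, window.end)
    observed = scanpath_string(fixations, aois, collapse=collapse, onset=onset, window=win)
    sim = similarity_ratio(observed.symbols, aois.intended_sequence)
    return TrialMetrics(
        participant=participant,
        trial=trial,
        condition=condition,
        aoi_metrics=per_aoi,
        observed_sequence=observed.symbols,
        intended_sequence=aois.intended_sequence,
        similarity=sim,
        excluded=excluded,
    )


def is_first_of_block(trial_index: int, block_size: int = 4) -> bool:
    """First-trial-per-block exclusion rule (primacy-effect mitigation)."""
    return trial_index % block_size == 0


def metrics_table(trials: Iterable[TrialMetrics]) -> pd.DataFrame:
    """Tidy long table: one row per trial x metric (x AOI for AOI metrics).

    ``metric`` is one of ttff / dwell / n_fix (with an ``aoi`` value) or
    distance / similarity / similarity_pct (aoi empty). Missing TTFF is NaN.
    """
    rows = []
    for tm in trials:
        base = {
            "participant": tm.participant,
            "trial": tm.trial,
            "condition": tm.condition,
            "excluded": tm.excluded,
        }
        for label, am in tm.aoi_metrics.items():
            for metric, value in (
                ("ttff", np.nan if am.ttff is None else am.ttff),
                ("dwell", am.dwell),
                ("n_fix", am.n_fixations),
            ):
                rows.append({**base, "metric": metric, "aoi": label, "value": value})
        for metric, value in (
            ("distance", tm.similarity.distance),
            ("similarity", tm.similarity.ratio),
            ("similarity_pct", tm.similarity.ratio_percent),
        ):
            rows.append({**base, "metric": metric, "aoi": "", "value": value})
    return pd.DataFrame(
        rows,
        columns=["participant", "trial", "condition", "excluded", "metric", "aoi", "value"],
    )
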