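"""Areas of Interest: geometry, fixation assignment, scanpath strings.

AOIs are labelled screen regions (axis-aligned rectangles or polygons, pixel
coordinates, origin top-left, y increasing downward). A fixation belongs to
the AOI containing its centroid, with boundaries inclusive; AOI sets are
validated to be non-overlapping at load so that containment is unambiguous.
Scanpath strings are the ordered AOI labels visited by a trial's fixations,
with consecutive repeats collapsed by default (a scanpath records AOI visits,
not individual fixations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from shapely.geometry import Point, Polygon, box

if TYPE_CHECKING:  # pragma: no cover
    from .fixation import Fixation

__all__ = ["AOI", "AOISet", "ScanpathString", "assign_fixation", "scanpath_string"]


@dataclass(frozen=True)
class AOI:
    """One labelled region: a rectangle (x, y, w, h) or a polygon vertex list."""

    label: str
    rect: tuple[float, float, float, float] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.label, str) and len(self.label) == 1):
            raise ValueError(f"AOI label must be a single symbol, got {self.label!r}")
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("exactly one of rect or polygon must be given")
        if self.rect is not None:
            x, y, w, h = self.rect
            if w <= 0 or h <= 0:
                raise ValueError(f"AOI {self.label!r} rect must have positive area")
        if self.shape.area <= 0:
            raise ValueError(f"AOI {self.label!r} must have positive area")

    @property
    def shape(self) -> Polygon:
        if self.rect is not None:
            x, y, w, h = self.rect
            return box(x, y, x + w, y + h)
        return Polygon(self.polygon)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.shape.centroid
        return (float(c.x), float(c.y))

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive containment."""
        return bool(self.shape.covers(Point(float(x), float(y))))


@dataclass(frozen=True)
class AOISet:
    """All AOIs of one stimulus plus its hypothesised (intended) visit order."""

    stimulus: str
    aois: tuple[AOI, ...]
    intended_sequence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "aois", tuple(self.aois))
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate AOI labels in stimulus {self.stimulus!r}")
        missing = [c for c in self.intended_sequence if c not in labels]
        if missing:
            raise ValueError(
                f"intended_sequence symbols {missing} not among AOI labels {labels}"
            )
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1 :]:
                if a.shape.intersection(b.shape).area > 0:
                    raise ValueError(
                        f"AOIs {a.label!r} and {b.label!r} overlap in "
                        f"stimulus {self.stimulus!r}"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.aois)

    def __getitem__(self, label: str) -> AOI:
        for a in self.aois:
            if a.label == label:
                return a
        raise KeyError(f"unknown AOI label {label!r} in stimulus {self.stimulus!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def assign_point(self, x: float, y: float) -> str | None:
        hits = [a.label for a in self.aois if a.contains(x, y)]
        if len(hits) > 1:
            raise ValueError(
                f"point ({x}, {y}) lies in multiple AOIs {hits}; "
                "overlapping AOIs should have been rejected at load"
            )
        return hits[0] if hits else None


@dataclass(frozen=True)
class ScanpathString:
    """Ordered AOI labels visited in a trial, with per-symbol fixation indices."""

    symbols: str
    sources: tuple[tuple[int, ...], ...] = ()

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols


def assign_fixation(fix: "Fixation", aois: AOISet) -> str | None:
    """Label of the AOI containing the fixation centroid, or None."""
    return aois.assign_point(fix.centroid_x, fix.centroid_y)


def scanpath_string(
    fixations: Sequence["Fixation"],
    aois: AOISet,
    collapse: bool = True,
    onset: float = 0.0,
    window: tuple[float, float | None] | None = None,
) -> ScanpathString:
    """Build the AOI visit sequence from a trial's ordered fixations.

    Fixations starting before ``onset + window[0]`` (default: the stimulus
    onset) or at/after ``onset + window[1]`` (when bounded) are ignored, as are
    fixations whose centroid lies outside every AOI. With ``collapse=True``
    consecutive identical labels merge into one symbol whose source indices
    are the contributing fixations.
    """
    w_start, w_end = window if window is not None else (0.0, None)
    symbols: list[str] = []
    sources: list[list[int]] = []
    for i, fix in enumerate(fixations):
        if fix.start < onset + w_start:
            continue
        if w_end is not None and fix.start >= onset + w_end:
            continue
        label = assign_fixation(fix, aois)
        if label is None:
            continue
        if collapse and symbols and symbols[-1] == label:
            sources[-1].append(i)
        else:
            symbols.append(label)
            sources.append([i])
    return ScanpathString("".join(symbols), tuple(tuple(s) for s in sources))
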