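"""Scanpath string alignment: Levenshtein distance and similarity ratio.

The distance is the classic unit-cost edit distance (insertions, deletions,
substitutions; no transpositions). The similarity ratio normalises it by the
length of the longer sequence:

    ratio = 1 - distance / max(|a|, |b|)

so 1.0 means identical sequences and 0.0 maximal dissimilarity. Two empty
sequences are identical by definition (ratio 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SimilarityResult", "levenshtein", "similarity_ratio"]


@dataclass(frozen=True)
class SimilarityResult:
    """Edit distance between two sequences plus its normalised form."""

    distance: int
    longer_length: int
    ratio: float

    @property
    def ratio_percent(self) -> float:
        return 100.0 * self.ratio


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Minimum number of single-symbol edits transforming ``a`` into ``b``.

    Iterative dynamic programming over two rows; O(|a| * |b|) time,
    O(min(|a|, |b|)) space. Symmetric; 0 iff the sequences are equal.
    """
    if len(a) < len(b):
        a, b = b, a
    if len(b) == 0:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != cb),  # substitution / match
            )
        prev = cur
    return prev[-1]


def similarity_ratio(a: Sequence, b: Sequence) -> SimilarityResult:
    """Similarity between two sequences as 1 - distance / longer length."""
    dist = levenshtein(a, b)
    longer = max(len(a), len(b))
    ratio = 1.0 if longer == 0 else 1.0 - dist / longer
    return SimilarityResult(distance=dist, longer_length=longer, ratio=ratio)
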