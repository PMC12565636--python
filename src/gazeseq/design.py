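"""Counterbalanced trial ordering (Latin squares) and experiment design.

``latin_square_orders`` builds presentation orders in blocks of ``k`` rows,
each block a cyclic Latin square, so every condition appears exactly once in
every ordinal position within a block. Blocks alternate between a Williams
(carryover-balanced) square and its negated-offset companion; for even k ≥ 4
this yields 2k distinct row orderings across two blocks. (The Williams square
itself is closed under row reversal for even k, so "square plus reversed rows"
would not give new orderings — the negated-offset square is the standard
alternative and is itself carryover-balanced.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["latin_square_orders", "ExperimentDesign", "DEFAULT_CONDITIONS"]

DEFAULT_CONDITIONS: tuple[str, ...] = (
    "color_bright",
    "color_dull",
    "layered",
    "non_layered",
    "line_connected",
    "line_plain",
    "size_graded",
    "size_equal",
)


def _williams_offsets(k: int) -> np.ndarray:
    # Column offsets 0, +1, -1, +2, -2, ... (mod k); a permutation for every k,
    # carryover-balanced for even k.
    g = np.empty(k, dtype=int)
    g[0] = 0
    for j in range(1, k):
        g[j] = (j + 1) // 2 if j % 2 == 1 else -(j // 2)
    return g % k


def latin_square_orders(k: int, n_sequences: int) -> np.ndarray:
    """Condition-index orders for ``n_sequences`` participants over ``k`` conditions.

    Returns an (n_sequences, k) integer array. ``n_sequences`` must be a
    multiple of ``k``: orders are produced in blocks of k rows, each block a
    Latin square (every condition once per ordinal position).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n_sequences < 1 or n_sequences % k != 0:
        raise ValueError(
            f"n_sequences must be a positive multiple of k={k}, got {n_sequences}"
        )
    g = _williams_offsets(k)
    g_neg = (-g) % k
    rows = []
    for block in range(n_sequences // k):
        offsets = g if block % 2 == 0 else g_neg
        for i in range(k):
            rows.append((i + offsets) % k)
    return np.array(rows, dtype=int)


@dataclass(frozen=True)
class ExperimentDesign:
    """Within-subjects design: participants x trials with counterbalanced order.

    Defaults emulate a 34-participant, 8-condition (4 strategies x A/B variant)
    brief-exposure study sampled at 120 Hz, i.e. 272 trials in total.
    """

    n_participants: int = 34
    n_trials: int = 8
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    ordering: str = "latin_square"
    sampling_rate: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("n_participants and n_trials must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.ordering not in ("latin_square", "fixed", "shuffled"):
            raise ValueError(f"unknown ordering {self.ordering!r}")
        if self.ordering == "latin_square" and self.n_trials != len(self.conditions):
            raise ValueError(
                "latin_square ordering requires n_trials == number of conditions "
                f"({self.n_trials} != {len(self.conditions)})"
            )

    def participant_orders(self) -> np.ndarray:
        """(n_participants, n_trials) array of condition indices."""
        k = len(self.conditions)
        if self.ordering == "latin_square":
            n_blocks = -(-self.n_participants // k)  # ceil
            return latin_square_orders(k, n_blocks * k)[: self.n_participants]
        if self.ordering == "fixed":
            return np.tile(np.arange(self.n_trials) % k, (self.n_participants, 1))
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0x0BDE)))
        return np.array(
            [rng.permutation(self.n_trials) % k for _ in range(self.n_participants)]
        )
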