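"""Block-design task schedules for the corticospinal fMRI experiment.

The experiment alternates unilateral finger-opposition blocks (right-hand
movement, RHM, and left-hand movement, LHM) with resting blocks, sampled at a
repetition time (TR) of 2.6 s.  The default schedule is 8 task blocks
(alternating RHM/LHM, starting with RHM) interleaved with 9 rest blocks of
11 TRs (28.6 s) each, for a 187-TR run.

All timing is expressed in 0-based TR indices with half-open block windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Anatomical region labels, in canonical storage order.
REGIONS = (
    "M1_L",
    "M1_R",
    "SHc_L_C5",
    "SHc_R_C5",
    "SHc_L_C7Th1",
    "SHc_R_C7Th1",
)

HANDS = ("RHM", "LHM")
REST = "rest"

#: C5 spinal hemicord regions carry no hand-motoneuron signal (control level).
CONTROL_REGIONS = ("SHc_L_C5", "SHc_R_C5")


def contra_m1(hand: str) -> str:
    """M1 contralateral to the moving hand (crossed corticospinal tract)."""
    return {"RHM": "M1_L", "LHM": "M1_R"}[hand]


def ipsi_m1(hand: str) -> str:
    """M1 ipsilateral to the moving hand."""
    return {"RHM": "M1_R", "LHM": "M1_L"}[hand]


def ipsi_shc(hand: str, segment: str = "C7Th1") -> str:
    """Spinal hemicord on the side of the moving hand at the given segment."""
    side = {"RHM": "R", "LHM": "L"}[hand]
    return f"SHc_{side}_{segment}"


def contra_shc(hand: str, segment: str = "C7Th1") -> str:
    """Spinal hemicord opposite to the moving hand at the given segment."""
    side = {"RHM": "L", "LHM": "R"}[hand]
    return f"SHc_{side}_{segment}"


def other_hand(hand: str) -> str:
    return {"RHM": "LHM", "LHM": "RHM"}[hand]


@dataclass(frozen=True)
class BlockDesign:
    """A contiguous rest/task block schedule in TR units.

    Parameters
    ----------
    tr_seconds
        Repetition time in seconds.
    onsets
        Tuple of ``(start_tr, n_trs, condition)`` triples covering the run
        contiguously; ``condition`` is ``"rest"``, ``"RHM"`` or ``"LHM"``.
    """

    tr_seconds: float
    onsets: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.onsets:
            raise ValueError("design has no blocks")
        cursor = 0
        for start, n, cond in self.onsets:
            if start != cursor:
                raise ValueError(
                    f"blocks must be contiguous and non-overlapping; block at "
                    f"{start} does not start at {cursor}"
                )
            if n < 1:
                raise ValueError("every block needs at least one TR")
            if cond not in (REST,) + HANDS:
                raise ValueError(f"unknown block condition {cond!r}")
            cursor += n

    @property
    def n_trs(self) -> int:
        return sum(n for _, n, _ in self.onsets)

    @property
    def duration_seconds(self) -> float:
        return self.n_trs * self.tr_seconds

    def blocks(self, condition: str) -> list[tuple[int, int]]:
        """(start, n_trs) for every block with the given condition label."""
        return [(s, n) for s, n, c in self.onsets if c == condition]

    def task_blocks(self, hand: str) -> list[tuple[int, int]]:
        if hand not in HANDS:
            raise ValueError(f"unknown hand {hand!r}")
        return self.blocks(hand)

    def rest_blocks_before(self, hand: str) -> list[tuple[int, int]]:
        """The rest block immediately preceding each task block of `hand`.

        These are the rest epochs paired with that hand in the task-vs-rest
        connectivity contrasts.
        """
        out = []
        for i, (start, n, cond) in enumerate(self.onsets):
            if cond == hand and i > 0:
                ps, pn, pc = self.onsets[i - 1]
                if pc == REST:
                    out.append((ps, pn))
        if not out:
            raise ValueError(f"no rest block precedes any {hand} block")
        return out

    def boxcar(self, hand: str) -> np.ndarray:
        """0/1 indicator of the task blocks of one hand, length ``n_trs``."""
        x = np.zeros(self.n_trs)
        for start, n in self.task_blocks(hand):
            x[start : start + n] = 1.0
        return x

    def __iter__(self) -> Iterator[tuple[int, int, str]]:
        return iter(self.onsets)


def make_design(
    tr_seconds: float = 2.6,
    n_task_blocks: int = 8,
    n_rest_blocks: int = 9,
    task_block_trs: int = 11,
    rest_block_trs: int = 11,
    strict_alternation: bool = True,
) -> BlockDesign:
    """Build the alternating rest/RHM/rest/LHM/... schedule.

    The run begins and ends with rest; hand labels alternate RHM, LHM, RHM, ...
    Defaults reproduce the experimental protocol: TR 2.6 s, 8 task blocks and
    9 rest blocks of 11 TRs (28.6 s) each, 187 TRs in total.

    Raises
    ------
    ValueError
        For non-positive counts, if ``n_rest_blocks != n_task_blocks + 1``,
        or for an odd number of task blocks under strict alternation (the two
        hands would then get unequal numbers of blocks).
    """
    if min(n_task_blocks, n_rest_blocks, task_block_trs, rest_block_trs) < 1:
        raise ValueError("all block counts and lengths must be >= 1")
    if n_rest_blocks != n_task_blocks + 1:
        raise ValueError(
            "the alternating layout requires n_rest_blocks == n_task_blocks + 1"
        )
    if strict_alternation and n_task_blocks % 2:
        raise ValueError(
            "odd n_task_blocks cannot give both hands equal block counts; "
            "pass strict_alternation=False to allow it"
        )
    onsets: list[tuple[int, int, str]] = []
    cursor = 0
    for i in range(n_task_blocks):
        onsets.append((cursor, rest_block_trs, REST))
        cursor += rest_block_trs
        hand = HANDS[i % 2]
        onsets.append((cursor, task_block_trs, hand))
        cursor += task_block_trs
    onsets.append((cursor, rest_block_trs, REST))
    return BlockDesign(tr_seconds=tr_seconds, onsets=tuple(onsets))
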