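"""Scanning-speller session planning.

The speller presents a 6 x 6 character matrix and a selector bar that sweeps
the columns left to right, then the rows bottom to top.  The *cue* for a
trial is the moment the bar enters the column (or row) containing the target
character; the subject is expected to dorsiflex when the bar is around the
middle of that cell, i.e. ``midpoint_offset_s`` after the cue.  Each
13-character phrase therefore yields 26 cues = 26 candidate movement-related
cortical potentials (MRCPs).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GRID_SIZE",
    "PHRASE",
    "CONTROL_PHRASE",
    "CONDITIONS",
    "SpellerLayout",
    "TimingSpec",
    "CueEvent",
    "SessionPlan",
    "build_layout",
    "plan_condition",
    "simulate_session",
]

GRID_SIZE = 6

#: the copy-spelling phrase; the control condition repeats 'O' 13 times and
#: the random condition is a seeded anagram of the phrase.
PHRASE = "HELLO IM FINE"
CONTROL_PHRASE = "O" * len(PHRASE)
CONDITIONS = ("control", "phrase", "random")

EVENT_COLUMNS = ["onset_s", "type", "target_char", "trial_idx", "condition"]


@dataclass(frozen=True)
class SpellerLayout:
    """6 x 6 character grid with column/row lookup.

    ``grid[row][col]`` is the character at that cell; row 0 is the top row.
    """

    grid: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.grid) != GRID_SIZE or any(len(r) != GRID_SIZE for r in self.grid):
            raise ValueError("layout must be a 6 x 6 grid")
        chars = "".join(self.grid)
        if len(set(chars)) != GRID_SIZE * GRID_SIZE:
            raise ValueError("layout cells must be 36 distinct characters")

    def cell_of(self, char: str) -> tuple[int, int]:
        """Return ``(column, row)`` of ``char`` (0-based, row 0 = top)."""
        for row, row_chars in enumerate(self.grid):
            col = row_chars.find(char)
            if col >= 0:
                return col, row
        raise KeyError(f"character {char!r} not in speller layout")

    def __contains__(self, char: str) -> bool:
        return any(char in row for row in self.grid)


@dataclass(frozen=True)
class TimingSpec:
    """Selector-bar kinematics.

    dwell_s
        Time the bar spends traversing one cell; the selection of a
        column/row lasts this long.
    pause_s
        Pause after each column/row selection before the next sweep starts.
    midpoint_offset_s
        Expected movement time after cue onset (the bar is around the cell
        midpoint then).
    lead_in_s
        Recording time before the first sweep starts, so the earliest cue
        still admits a full pre-cue epoch window.
    """

    dwell_s: float = 2.0
    pause_s: float = 2.0
    midpoint_offset_s: float = 1.0
    lead_in_s: float = 5.0

    def __post_init__(self) -> None:
        if min(self.dwell_s, self.pause_s, self.midpoint_offset_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.midpoint_offset_s > self.dwell_s:
            raise ValueError("midpoint_offset_s cannot exceed dwell_s")
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s must be non-negative")


@dataclass(frozen=True)
class CueEvent:
    onset_s: float
    type: str  # 'column' | 'row'
    target_char: str
    trial_idx: int


@dataclass(frozen=True)
class SessionPlan:
    """Ordered cue events for one phrase under one condition."""

    condition: str
    phrase: str
    events: tuple[CueEvent, ...]
    timing: TimingSpec = field(default_factory=TimingSpec)

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "type": [e.type for e in self.events],
                "target_char": [e.target_char for e in self.events],
                "trial_idx": [e.trial_idx for e in self.events],
                "condition": self.condition,
            },
            columns=EVENT_COLUMNS,
        )


def build_layout() -> SpellerLayout:
    """Default layout: A-Z row-major, then digits 0-8, then space."""
    chars = string.ascii_uppercase + "012345678" + " "
    rows = tuple(chars[i * GRID_SIZE : (i + 1) * GRID_SIZE] for i in range(GRID_SIZE))
    return SpellerLayout(rows)


def plan_condition(condition: str, seed: int = 0) -> str:
    """Phrase for a named condition.

    control -> 13 repeated 'O'; phrase -> the copy-spelling phrase;
    random -> a seeded shuffle (anagram) of the copy-spelling phrase.
    """
    if condition == "control":
        return CONTROL_PHRASE
    if condition == "phrase":
        return PHRASE
    if condition == "random":
        chars = list(PHRASE)
        random.Random(seed).shuffle(chars)
        return "".join(chars)
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def simulate_session(
    phrase: str,
    layout: SpellerLayout | None = None,
    timing: TimingSpec | None = None,
    condition: str = "custom",
) -> SessionPlan:
    """Plan the cue event stream for spelling ``phrase``.

    For each character the bar sweeps the columns left to right (cue when it
    enters the target column), dwells one cell width to complete the
    selection, pauses, then sweeps the rows bottom to top (cue at row entry),
    dwells, and pauses again before the next character.  Every cue is one
    trial, so a 13-character phrase yields 26 strictly increasing events.
    """
    layout = layout or build_layout()
    timing = timing or TimingSpec()
    events: list[CueEvent] = []
    t = timing.lead_in_s
    trial = 0
    for char in phrase:
        col, row = layout.cell_of(char)  # KeyError if absent
        # column sweep, left -> right
        cue = t + col * timing.dwell_s
        events.append(CueEvent(cue, "column", char, trial))
        trial += 1
        t = cue + timing.dwell_s + timing.pause_s
        # row sweep, bottom -> top: bottom row (index GRID_SIZE-1) is entered first
        cue = t + (GRID_SIZE - 1 - row) * timing.dwell_s
        events.append(CueEvent(cue, "row", char, trial))
        trial += 1
        t = cue + timing.dwell_s + timing.pause_s
    return SessionPlan(condition=condition, phrase=phrase, events=tuple(events), timing=timing)
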