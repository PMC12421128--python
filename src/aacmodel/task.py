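"""Structure of the approach-avoidance conflict (AAC) runway task.

The task presents an avatar on a nine-position runway with an outcome cue at
each end.  Moving toward a cue raises the probability of that cue's outcome in
10% steps: the position adjacent to a cue delivers its outcome with
probability 0.9, the far position with probability 0.1.  Five trial types are
defined by the pair of end outcomes:

========  =========================  =====================
type      high-end outcome           low-end outcome
========  =========================  =====================
AV        negative, 0 points         positive, 0 points
APP       positive, 2 points         positive, 0 points
CONF2     negative, 2 points         positive, 0 points
CONF4     negative, 4 points         positive, 0 points
CONF6     negative, 6 points         positive, 0 points
========  =========================  =====================

Positions use a canonical high/low frame: position 9 is adjacent to the
high-end cue (the reward-bearing or aversive side), position 1 to the safe
low end, so larger mean chosen position means more approach behavior.  The
physical left/right placement of cues is recorded for display semantics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_TYPES = ("AV", "APP", "CONF2", "CONF4", "CONF6")
CUE_SIDES = ("left", "right")
START_POSITIONS = ("center", "left_end", "right_end")
N_POSITIONS = 9


@dataclass(frozen=True)
class Outcome:
    """A terminal observation: affective valence plus reward points."""

    valence: str
    points: int

    def __post_init__(self) -> None:
        if self.valence not in ("positive", "negative", "starting"):
            raise ValueError(f"invalid valence {self.valence!r}")
        allowed = {
            "positive": (0, 2),
            "negative": (0, 2, 4, 6),
            "starting": (0,),
        }[self.valence]
        if self.points not in allowed:
            raise ValueError(
                f"points={self.points} invalid for valence={self.valence!r}"
            )

    def __str__(self) -> str:  # e.g. "neg+4"
        tag = {"positive": "pos", "negative": "neg", "starting": "start"}
        return f"{tag[self.valence]}+{self.points}"


#: Sentinel observation seen before any outcome is delivered.
STARTING = Outcome("starting", 0)


def enumerate_outcomes() -> tuple[Outcome, ...]:
    """The fixed ordered set of seven observations.

    Index 0 is the starting sentinel, then the two positive outcomes
    (0 and 2 points) and the four negative outcomes (0, 2, 4, 6 points).
    """
    return (
        STARTING,
        Outcome("positive", 0),
        Outcome("positive", 2),
        Outcome("negative", 0),
        Outcome("negative", 2),
        Outcome("negative", 4),
        Outcome("negative", 6),
    )


OUTCOMES = enumerate_outcomes()
OUTCOME_INDEX = {o: i for i, o in enumerate(OUTCOMES)}

_HIGH_END = {
    "AV": Outcome("negative", 0),
    "APP": Outcome("positive", 2),
    "CONF2": Outcome("negative", 2),
    "CONF4": Outcome("negative", 4),
    "CONF6": Outcome("negative", 6),
}
_LOW_END = Outcome("positive", 0)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: a trial type plus display counterbalancing attributes."""

    trial_type: str
    high_cue_side: str = "right"
    start_position: str = "center"

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.high_cue_side not in CUE_SIDES:
            raise ValueError(f"invalid cue side {self.high_cue_side!r}")
        if self.start_position not in START_POSITIONS:
            raise ValueError(f"invalid start position {self.start_position!r}")

    @property
    def high_end_outcome(self) -> Outcome:
        return _HIGH_END[self.trial_type]

    @property
    def low_end_outcome(self) -> Outcome:
        return _LOW_END


@dataclass
class TaskDesign:
    """An ordered sequence of trials plus the runway geometry."""

    trials: list[TrialSpec] = field(default_factory=list)
    n_positions: int = N_POSITIONS

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def validate(self) -> None:
        """Check per-type counts are equal and counterbalancing is even."""
        counts = pd.Series([t.trial_type for t in self.trials]).value_counts()
        if set(counts.index) != set(TRIAL_TYPES) or counts.nunique() != 1:
            raise ValueError("trial types not balanced")
        n = counts.iloc[0]
        for ttype in TRIAL_TYPES:
            sides = [t.high_cue_side for t in self.trials if t.trial_type == ttype]
            n_left = sides.count("left")
            # cue side alternates as evenly as parity allows
            if abs(n_left - (n - n_left)) > 1:
                raise ValueError(f"cue side unbalanced within {ttype}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(self.trials)),
                "trial_type": [t.trial_type for t in self.trials],
                "high_cue_side": [t.high_cue_side for t in self.trials],
                "start_position": [t.start_position for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaskDesign":
        frame = frame.sort_values("trial_index")
        trials = [
            TrialSpec(r.trial_type, r.high_cue_side, r.start_position)
            for r in frame.itertuples()
        ]
        return cls(trials)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TaskDesign":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"))

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        return cls.from_frame(pd.DataFrame(json.loads(text)))


def build_task_design(seed: int, n_per_type: int = 12) -> TaskDesign:
    """Build a balanced, seed-shuffled task design.

    Each of the five trial types contributes ``n_per_type`` trials.  Within a
    type, cue side alternates left/right and the start position cycles through
    center / left end / right end, then the full trial order is shuffled with
    the given seed.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    trials: list[TrialSpec] = []
    for ttype in TRIAL_TYPES:
        for i in range(n_per_type):
            trials.append(
                TrialSpec(
                    ttype,
                    high_cue_side=CUE_SIDES[i % 2],
                    start_position=START_POSITIONS[i % 3],
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return TaskDesign([trials[i] for i in order])


def outcome_probabilities(position: int, trial: TrialSpec) -> tuple[float, float]:
    """Probability pair (p_high, p_low) for a final runway position.

    Position 9 sits next to the high-end cue (p_high = 0.9); position 1 next
    to the low-end cue (p_high = 0.1).  The trial argument fixes which
    outcomes the two ends carry; the probabilities themselves depend only on
    position.
    """
    if int(position) != position or not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position must be an integer in 1..9, got {position}")
    p_high = position / 10.0
    return p_high, 1.0 - p_high
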