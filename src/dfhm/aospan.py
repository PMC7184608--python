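"""Automated operation-span (AOSPAN) scoring.

The task interleaves letter memorization with math verification. The
working-memory measure is the *absolute score*: the sum of set lengths
over only those sets recalled perfectly in serial order. The math
time limit for the main task is calibrated per subject from practice
response times as mean + 2.5 × sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SetOutcome", "AOSPANResult", "aospan_score", "math_time_limit"]


@dataclass(frozen=True)
class SetOutcome:
    """One memory set: letters shown, letters recalled, math correctness."""

    presented: tuple[str, ...]
    recalled: tuple[str, ...]
    math_correct: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.recalled) > len(self.presented):
            raise ValueError("recall longer than presentation")

    @property
    def perfect(self) -> bool:
        return self.recalled == self.presented


@dataclass
class AOSPANResult:
    set_outcomes: list[SetOutcome]
    absolute_score: int
    math_accuracy: float | None  # percent, None when no math judgments exist

    def __post_init__(self) -> None:
        total = sum(len(s.presented) for s in self.set_outcomes)
        if self.absolute_score > total:
            raise ValueError("absolute score exceeds letters presented")


def aospan_score(outcomes) -> AOSPANResult:
    """Score a list of :class:`SetOutcome`.

    A set contributes its full length iff every letter was recalled in the
    correct serial position; any deviation (including a single transposition)
    contributes zero. Math accuracy is the percentage of correct judgments
    across all sets, or None (flagged missing) when there are none.
    """
    outcomes = list(outcomes)
    score = sum(len(s.presented) for s in outcomes if s.perfect)
    flags = [f for s in outcomes for f in s.math_correct]
    accuracy = 100.0 * float(np.mean(flags)) if flags else None
    return AOSPANResult(set_outcomes=outcomes, absolute_score=score, math_accuracy=accuracy)


def math_time_limit(practice_rts) -> float:
    """Per-subject math time limit: mean(practice RTs) + 2.5 × sample SD."""
    rts = np.asarray(list(practice_rts), dtype=float)
    if rts.size < 2:
        raise ValueError("need at least 2 practice response times")
    return float(rts.mean() + 2.5 * rts.std(ddof=1))
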