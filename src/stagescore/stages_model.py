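"""The STAGES level grid and the mapping from three answers to a level.

The STAGES model of ego development places a sentence on a 12-level scale
running from 1.0 to 6.5 in half steps.  A level is determined by three
categorical judgements about the sentence:

* **Q1 — tier of object awareness**: Concrete (1), Subtle (2) or
  MetAware (3).  Each tier owns a block of four consecutive levels
  (Concrete 1.0–2.5, Subtle 3.0–4.5, MetAware 5.0–6.5).
* **Q2 — person perspective**: Individual (1) or Collective (2).  The
  collective focus adds one whole step within the tier block.
* **Q3 — agency**: Passive (1) or Active (2).  The active orientation adds
  a half step.

The decision tree over the three answers is therefore the closed form

    level = 2 * (q1 - 1) + q2 + 0.5 * (q3 - 1)

which is the unique order-consistent assignment of (tier, person, agency)
triples onto the half-step grid: it is a bijection between the 12 possible
triples and the 12 levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidAnswerError, InvalidLevelError, InvalidValueError

#: The 12 STAGES levels, strictly ordered.  Half steps are exact in binary
#: floating point, so float equality against grid members is safe.
GRID: tuple[float, ...] = tuple(1.0 + 0.5 * i for i in range(12))

#: Level value -> 0-based grid index.
LEVEL_INDEX: dict[float, int] = {level: i for i, level in enumerate(GRID)}

#: Valid code range per question.
QUESTION_RANGES: dict[int, tuple[int, int]] = {1: (1, 3), 2: (1, 2), 3: (1, 2)}


@dataclass(frozen=True)
class TripleAnswer:
    """The (Q1, Q2, Q3) category codes of one classification run.

    q1: tier code, 1=Concrete, 2=Subtle, 3=MetAware.
    q2: person code, 1=Individual, 2=Collective.
    q3: agency code, 1=Passive, 2=Active.
    """

    q1: int
    q2: int
    q3: int

    def __post_init__(self) -> None:
        for qid, code in ((1, self.q1), (2, self.q2), (3, self.q3)):
            lo, hi = QUESTION_RANGES[qid]
            if not isinstance(code, int) or not lo <= code <= hi:
                raise InvalidAnswerError(
                    f"Q{qid} code must be an integer in [{lo}, {hi}], got {code!r}"
                )


def is_on_grid(x: float) -> bool:
    """True if ``x`` is one of the 12 STAGES levels."""
    return x in LEVEL_INDEX


def validate_level(x: float) -> float:
    """Return ``x`` unchanged if it is on the grid, else raise."""
    if not is_on_grid(x):
        raise InvalidLevelError(
            f"{x!r} is not on the STAGES grid {GRID[0]}..{GRID[-1]} (half steps)"
        )
    return float(x)


def level_index(x: float) -> int:
    """0-based grid position of a level (0 for 1.0 ... 11 for 6.5)."""
    validate_level(x)
    return LEVEL_INDEX[float(x)]


def level_from_answers(answer: TripleAnswer) -> float:
    """Map a (Q1, Q2, Q3) triple to its STAGES level.

    The map is a bijection onto the grid: tier selects a block of four
    levels, the collective focus adds 1.0 within the block, the active
    orientation adds 0.5.
    """
    if not isinstance(answer, TripleAnswer):
        answer = TripleAnswer(*answer)
    return 2.0 * (answer.q1 - 1) + answer.q2 + 0.5 * (answer.q3 - 1)


def answers_from_level(level: float) -> TripleAnswer:
    """Inverse of :func:`level_from_answers` (exact on grid members)."""
    idx = level_index(level)
    q1 = idx // 4 + 1
    q2 = (idx % 4) // 2 + 1
    q3 = idx % 2 + 1
    return TripleAnswer(q1, q2, q3)


def snap_to_grid(x: float) -> float:
    """Round a real score to the nearest STAGES level.

    Exact midpoints between two levels round up (half-up on ``2 * x``), and
    the result is clamped to [1.0, 6.5].  Used to place an averaged score
    back onto the half-step scale.
    """
    if not isinstance(x, (int, float)) or not math.isfinite(x):
        raise InvalidValueError(f"cannot snap non-finite value {x!r} to the grid")
    snapped = math.floor(2.0 * x + 0.5) / 2.0
    return min(max(snapped, GRID[0]), GRID[-1])
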