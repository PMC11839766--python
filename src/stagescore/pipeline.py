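"""Per-sentence multi-run scoring with median stabilization, and
respondent-level aggregation.

A remote classifier at temperature 0 is still not perfectly deterministic,
so each sentence is classified ``n_runs`` times (10 by default, the point
at which the median outcome stabilizes) and the sentence's score is the
median of the per-run levels.  Medians here are always **lower medians**
(the element at position ceil(n/2) of the sorted list): for an even run
count an interpolated median could fall off the half-step grid, and a
sentence score must be an attainable STAGES level.

Respondents are positioned on the scale by the arithmetic mean of their
sentence scores, snapped back to the grid.  Five sentences are the accepted
minimum; ten are recommended.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    ClassificationFailedError,
    EmptyInputError,
    InsufficientItemsError,
    InvalidParameterError,
)
from .stages_model import TripleAnswer, level_from_answers, snap_to_grid

logger = logging.getLogger(__name__)

#: Accepted / recommended number of sentences per respondent.
MIN_SENTENCES = 5
RECOMMENDED_SENTENCES = 10

#: Default number of classification runs per sentence.
DEFAULT_N_RUNS = 10


@dataclass(frozen=True)
class SentenceRecord:
    """One test sentence, optionally with reference scores on the grid.

    ``map_score`` is an expert rating on the MAP (Cook-Greuter) system,
    which shares the 1.0–6.5 half-step scale; ``stages_score`` is a score
    produced by the automated STAGES protocol.
    """

    id: str
    text: str
    map_score: Optional[float] = None
    stages_score: Optional[float] = None


@dataclass
class SentenceClassification:
    """All runs for one sentence plus the stabilized outcome."""

    sentence_id: str
    runs: list[TripleAnswer]
    levels: list[float]
    median_q1: int
    median_q2: int
    median_q3: int
    median_level: float

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass(frozen=True)
class RespondentScore:
    """A respondent's position on the scale from their sentence scores."""

    respondent_id: str
    n_sentences: int
    mean_level: float
    snapped_level: float


def median_level(levels: Sequence[float]) -> float:
    """Lower median of a list of levels.

    Returns the element at position ceil(n/2) of the sorted list — always a
    value attained in the input, never interpolated.
    """
    if len(levels) == 0:
        raise EmptyInputError("median of an empty list is undefined")
    ordered = sorted(levels)
    return ordered[math.ceil(len(ordered) / 2) - 1]


def _lower_median_int(codes: Sequence[int]) -> int:
    ordered = sorted(codes)
    return ordered[math.ceil(len(ordered) / 2) - 1]


def classify_sentence(sentence: SentenceRecord,
                      backend,
                      n_runs: int = DEFAULT_N_RUNS,
                      seed: Optional[int] = None) -> SentenceClassification:
    """Classify one sentence ``n_runs`` times and stabilize by the median.

    Each run asks the backend the three STAGES questions and maps the triple
    to a level.  The sentence's score is the lower median of the per-run
    levels; per-question lower medians are recorded alongside because both
    series are of interest when calibrating run counts.  ``seed`` reseeds
    stochastic stub backends (those exposing a ``reseed`` method); genuinely
    deterministic backends ignore it.

    Runs in which any question yields an unparsable reply are dropped with a
    warning; if every run fails, :class:`ClassificationFailedError` is
    raised.
    """
    if not isinstance(n_runs, int) or n_runs < 1:
        raise InvalidParameterError(f"n_runs must be a positive integer, got {n_runs!r}")
    if seed is not None and hasattr(backend, "reseed"):
        backend.reseed(seed)
    runs: list[TripleAnswer] = []
    levels: list[float] = []
    for run_idx in range(n_runs):
        try:
            answer = TripleAnswer(*(backend.classify(sentence.text, qid) for qid in (1, 2, 3)))
        except Exception as exc:
            logger.warning("dropping run %d for sentence %s: %s", run_idx + 1, sentence.id, exc)
            continue
        runs.append(answer)
        levels.append(level_from_answers(answer))
    if not runs:
        raise ClassificationFailedError(
            f"all {n_runs} runs failed for sentence {sentence.id!r}"
        )
    return SentenceClassification(
        sentence_id=sentence.id,
        runs=runs,
        levels=levels,
        median_q1=_lower_median_int([a.q1 for a in runs]),
        median_q2=_lower_median_int([a.q2 for a in runs]),
        median_q3=_lower_median_int([a.q3 for a in runs]),
        median_level=median_level(levels),
    )


def classify_sentences(records: Sequence[SentenceRecord],
                       backend,
                       n_runs: int = DEFAULT_N_RUNS,
                       seed: Optional[int] = None) -> list[SentenceClassification]:
    """Classify a batch of sentences; seeds are derived per sentence so the
    result is independent of batch order for seeded stub backends."""
    out = []
    for i, rec in enumerate(records):
        run_seed = None if seed is None else (seed + i) % (2**31)
        out.append(classify_sentence(rec, backend, n_runs=n_runs, seed=run_seed))
    return out


def score_respondent(classifications: Sequence[SentenceClassification],
                     min_sentences: int = MIN_SENTENCES,
                     respondent_id: str = "respondent") -> RespondentScore:
    """Aggregate sentence scores into a respondent-level STAGES score.

    The respondent's position is the arithmetic mean of the per-sentence
    median levels, snapped to the half-step grid.
    """
    if min_sentences < 1:
        raise InvalidParameterError("min_sentences must be >= 1")
    if len(classifications) < min_sentences:
        raise InsufficientItemsError(
            f"{len(classifications)} sentences < required minimum {min_sentences}"
        )
    mean = sum(c.median_level for c in classifications) / len(classifications)
    return RespondentScore(
        respondent_id=respondent_id,
        n_sentences=len(classifications),
        mean_level=mean,
        snapped_level=snap_to_grid(mean),
    )
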