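"""Synthetic data with known ground truth.

Two generators:

* :func:`generate_paired_scores` — paired ordinal ratings under a
  copy-mixture model: rater A draws from a marginal over the 12-level grid;
  rater B copies A with probability ``a`` and otherwise draws independently
  from the same marginal.  The population quadratic-weighted kappa of this
  model equals ``a`` for *any* marginal (observed disagreement is (1-a)
  times the chance disagreement), giving an analytic target for estimator
  property tests.

* :func:`generate_sentences` — sentences assembled from the mock backend's
  own marker vocabulary so the mock pipeline recovers the intended
  (tier, person, agency) triple exactly.  These are a deterministic test
  harness for the pipeline, explicitly *not* a simulation of human
  sentence-completion responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidSpecError
from .pipeline import SentenceRecord
from .stages_model import GRID, TripleAnswer, answers_from_level, level_from_answers

#: Uniform marginal over the 12 levels.
UNIFORM_MARGINAL: tuple[float, ...] = tuple(1.0 / len(GRID) for _ in GRID)


@dataclass(frozen=True)
class MixturePairSpec:
    """Specification of the copy-mixture paired-rating model."""

    n: int
    marginal: Sequence[float] = UNIFORM_MARGINAL
    agreement: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        marg = np.asarray(self.marginal, dtype=float)
        if marg.shape != (len(GRID),):
            raise InvalidSpecError(f"marginal must have {len(GRID)} entries")
        if (marg < 0).any() or not np.isclose(marg.sum(), 1.0):
            raise InvalidSpecError("marginal must be non-negative and sum to 1")
        if not 0.0 <= self.agreement <= 1.0:
            raise InvalidSpecError("agreement must lie in [0, 1]")
        if self.n < 0:
            raise InvalidSpecError("n must be >= 0")


def generate_paired_scores(spec: MixturePairSpec) -> list[tuple[float, float]]:
    """Draw paired scores whose population weighted kappa equals
    ``spec.agreement``."""
    rng = np.random.default_rng(spec.seed)
    marg = np.asarray(spec.marginal, dtype=float)
    marg = marg / marg.sum()
    grid = np.asarray(GRID)
    a_idx = rng.choice(len(GRID), size=spec.n, p=marg)
    b_indep = rng.choice(len(GRID), size=spec.n, p=marg)
    copy = rng.random(spec.n) < spec.agreement
    b_idx = np.where(copy, a_idx, b_indep)
    return [(float(grid[i]), float(grid[j])) for i, j in zip(a_idx, b_idx)]


@dataclass(frozen=True)
class GeneratedSentence:
    """A synthetic sentence with its intended classification."""

    record: SentenceRecord
    intended: TripleAnswer
    level: float


# Template vocabulary.  Each slot is chosen so it triggers exactly the
# intended mock-backend rule and no other: subjects carry (or avoid) the
# collective markers, verbs carry (or avoid) the agentive markers, and
# objects carry the tier markers with precedence MetAware > Subtle >
# Concrete.
_SUBJECTS = {
    1: ("I", "She", "He", "The child", "My neighbor"),          # Individual
    2: ("The team", "The community", "The group", "The organization", "The family"),
}
_VERBS = {
    1: ("receives", "experiences", "notices", "is shown", "hears"),   # Passive
    2: ("builds", "creates", "shapes", "pursues", "chooses"),          # Active
}
_OBJECTS = {
    1: ("the red car", "a loud melody", "the wooden table", "a warm meal",
        "the garden gate"),                                            # Concrete
    2: ("a lasting sense of inner harmony", "the deeper meaning of this moment",
        "a quiet hope for lasting calm", "an ideal worth defending"),  # Subtle
    3: ("an awareness of hidden assumptions", "the constructs behind everyday experience",
        "a shift in the perception of what is real",
        "the biases woven into ordinary thought"),                     # MetAware
}


def sentence_for_answer(intended: TripleAnswer, rng: np.random.Generator) -> str:
    """Assemble one sentence the mock backend classifies as ``intended``."""
    subject = _SUBJECTS[intended.q2][rng.integers(len(_SUBJECTS[intended.q2]))]
    verb = _VERBS[intended.q3][rng.integers(len(_VERBS[intended.q3]))]
    obj = _OBJECTS[intended.q1][rng.integers(len(_OBJECTS[intended.q1]))]
    return f"{subject} {verb} {obj}."


def generate_sentences(n: int,
                       level_distribution: Sequence[float] = UNIFORM_MARGINAL,
                       seed: int = 0) -> list[GeneratedSentence]:
    """Generate ``n`` marker-bearing sentences with known STAGES levels.

    Levels are drawn from ``level_distribution`` over the grid; each level
    is inverted to its (Q1, Q2, Q3) triple and a sentence is assembled from
    the matching vocabulary so the mock pipeline recovers the level exactly.
    """
    dist = np.asarray(level_distribution, dtype=float)
    if dist.shape != (len(GRID),):
        raise InvalidSpecError(f"level_distribution must have {len(GRID)} entries")
    if (dist < 0).any() or not np.isclose(dist.sum(), 1.0):
        raise InvalidSpecError("level_distribution must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    out: list[GeneratedSentence] = []
    for i in range(n):
        level = float(np.asarray(GRID)[rng.choice(len(GRID), p=dist)])
        intended = answers_from_level(level)
        text = sentence_for_answer(intended, rng)
        rec = SentenceRecord(id=f"s-{i + 1}", text=text, stages_score=level)
        out.append(GeneratedSentence(record=rec, intended=intended, level=level))
    return out
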