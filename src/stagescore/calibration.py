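"""Calibration analyses for the scoring protocol.

Two questions are answered here:

1. **How many classification runs are enough?**  For each window of run
   counts [start, max_runs], regress the median classification outcome on
   the number of runs (ordinary least squares).  When the slope is flat for
   a window and every later window, extra runs no longer move the median —
   the stabilization point.

2. **How many sentences are enough?**  For each subsample size, draw random
   combinations from a full sentence set and measure how far the
   combination mean strays from the full-set mean (mean and standard
   deviation of the absolute differences).  The curve of these statistics
   against size shows where adding sentences stops buying precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    InvalidSizeError,
    InvalidWindowError,
)

#: Default regression windows: each start regresses up to max_runs.
DEFAULT_WINDOW_STARTS: tuple[int, ...] = (3, 5, 10, 15, 20)
DEFAULT_MAX_RUNS = 30

#: Quantity label for the aggregated level series.
STAGE_LEVEL = "STAGE level"

#: Default |slope| tolerance for calling a window flat.
DEFAULT_SLOPE_TOLERANCE = 0.005


@dataclass(frozen=True)
class RegressionRow:
    """OLS fit of median outcome (Y) on run count (X) over one window."""

    window_start: int
    quantity: str
    slope: float
    intercept: float


@dataclass(frozen=True)
class StabilizationResult:
    """Smallest window start from which all slopes stay within tolerance.

    ``stable`` is False when no such window exists; ``run_count`` then
    falls back to the configured maximum.
    """

    run_count: int
    stable: bool


@dataclass(frozen=True)
class SubsampleStat:
    """Distance between combination means and the full-set mean at one
    subsample size."""

    sample_size: int
    mean_abs_diff: float
    std_abs_diff: float
    n_combos: int


def run_count_regression(medians: Mapping[str, Mapping[int, float]],
                         window_starts: Sequence[int] = DEFAULT_WINDOW_STARTS,
                         max_runs: int = DEFAULT_MAX_RUNS) -> list[RegressionRow]:
    """OLS slope/intercept of median outcome vs run count per window.

    ``medians`` maps each quantity label (e.g. 'Q1', 'STAGE level') to a
    {run_count: median_outcome} series covering every run count from the
    smallest window start to ``max_runs``.
    """
    if not medians:
        raise EmptyInputError("no median series supplied")
    if not window_starts:
        raise InvalidWindowError("need at least one window start")
    if any(s < 3 for s in window_starts):
        raise InvalidWindowError("window starts must be >= 3")
    rows: list[RegressionRow] = []
    for quantity, series in medians.items():
        for start in window_starts:
            xs = list(range(start, max_runs + 1))
            if len(xs) < 2:
                raise InvalidWindowError(
                    f"window [{start}, {max_runs}] has fewer than 2 points"
                )
            try:
                ys = [series[x] for x in xs]
            except KeyError as exc:
                raise InvalidParameterError(
                    f"median series for {quantity!r} missing run count {exc.args[0]}"
                ) from exc
            fit = stats.linregress(xs, ys)
            rows.append(RegressionRow(
                window_start=start,
                quantity=quantity,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
            ))
    return rows


def stabilization_point(rows: Sequence[RegressionRow],
                        slope_tolerance: float = DEFAULT_SLOPE_TOLERANCE,
                        quantity: str = STAGE_LEVEL,
                        max_runs: int = DEFAULT_MAX_RUNS) -> StabilizationResult:
    """Smallest window start from which the level slopes stay flat.

    A window counts as flat when |slope| <= ``slope_tolerance``; the
    stabilization point is the smallest start whose window *and every later
    window* are flat.  When no start qualifies the result is flagged
    unstable and reports ``max_runs``.
    """
    relevant = sorted((r for r in rows if r.quantity == quantity),
                      key=lambda r: r.window_start)
    if not relevant:
        raise EmptyInputError(f"no regression rows for quantity {quantity!r}")
    for i, row in enumerate(relevant):
        if all(abs(later.slope) <= slope_tolerance for later in relevant[i:]):
            return StabilizationResult(run_count=row.window_start, stable=True)
    return StabilizationResult(run_count=max_runs, stable=False)


def subsample_stability(scores: Sequence[float],
                        sizes: Sequence[int] | None = None,
                        n_combos: int = 5000,
                        seed: int = 0) -> list[SubsampleStat]:
    """Stability of subsample means against the full-set mean.

    For each size, ``n_combos`` random combinations are drawn uniformly
    (without replacement within a combination; distinct combinations may
    repeat across draws) and |combination mean - full mean| is recorded.
    Returns the mean and population standard deviation of those absolute
    differences per size.  ``sizes`` defaults to 2..N-1.
    """
    scores_arr = np.asarray(scores, dtype=float)
    n = len(scores_arr)
    if n == 0:
        raise EmptyInputError("no scores supplied")
    if n_combos < 1:
        raise InvalidParameterError("n_combos must be >= 1")
    if sizes is None:
        sizes = range(2, n)
    full_mean = scores_arr.mean()
    rng = np.random.default_rng(seed)
    out: list[SubsampleStat] = []
    for size in sizes:
        if not 2 <= size <= n:
            raise InvalidSizeError(f"size must lie in [2, {n}], got {size}")
        if size == n:
            diffs = np.zeros(n_combos)
        else:
            idx = np.array([rng.choice(n, size=size, replace=False)
                            for _ in range(n_combos)])
            diffs = np.abs(scores_arr[idx].mean(axis=1) - full_mean)
        out.append(SubsampleStat(
            sample_size=int(size),
            mean_abs_diff=float(diffs.mean()),
            std_abs_diff=float(diffs.std()),  # population std: /n
            n_combos=n_combos,
        ))
    return out


def collect_run_medians(records, backend, max_runs: int = DEFAULT_MAX_RUNS,
                        min_runs: int = 3, seed: int = 0
                        ) -> dict[str, dict[int, float]]:
    """Build the median-vs-run-count series needed by
    :func:`run_count_regression` from live classifications.

    Each sentence is classified ``max_runs`` times; for every run count r in
    [min_runs, max_runs] the lower median over the first r runs is taken per
    question and for the level, then averaged over sentences.  Stochastic
    stub backends are reseeded per sentence so the series is reproducible.
    """
    from .pipeline import _lower_median_int, classify_sentence, median_level

    if not 1 <= min_runs <= max_runs:
        raise InvalidParameterError("need 1 <= min_runs <= max_runs")
    per_sentence: list[dict[str, dict[int, float]]] = []
    for i, rec in enumerate(records):
        cls = classify_sentence(rec, backend, n_runs=max_runs,
                                seed=(seed + i) % (2**31))
        series: dict[str, dict[int, float]] = {q: {} for q in ("Q1", "Q2", "Q3", STAGE_LEVEL)}
        for r in range(min_runs, max_runs + 1):
            prefix = cls.runs[:r]
            series["Q1"][r] = _lower_median_int([a.q1 for a in prefix])
            series["Q2"][r] = _lower_median_int([a.q2 for a in prefix])
            series["Q3"][r] = _lower_median_int([a.q3 for a in prefix])
            series[STAGE_LEVEL][r] = median_level(cls.levels[:r])
        per_sentence.append(series)
    n = len(per_sentence)
    if n == 0:
        raise EmptyInputError("no sentences supplied")
    return {
        q: {r: sum(s[q][r] for s in per_sentence) / n
            for r in range(min_runs, max_runs + 1)}
        for q in ("Q1", "Q2", "Q3", STAGE_LEVEL)
    }
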