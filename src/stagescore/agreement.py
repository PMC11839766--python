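"""Ordinal agreement statistics: cross-tabulation, quadratic-weighted
Cohen's kappa with its asymptotic standard error, and resampled
aggregate agreement.

Weighted kappa treats the 12 STAGES levels as ordered categories and
penalizes a disagreement of d grid steps by d^2 (quadratic weights), so a
half-step difference costs little while opposite-corner disagreements cost
the maximum:

    kappa = 1 - sum(w * p_obs) / sum(w * p_exp),   w_ij = (i - j)^2 / (k-1)^2

with ``p_exp`` the outer product of the empirical marginals.  The standard
error is the asymptotic non-null variance of Fleiss, Cohen & Everitt
(1969), and the 95% confidence interval is kappa +/- 1.96 se.

The aggregate-agreement procedure measures how well group-level averages
agree: random fixed-size combinations of sentence pairs are drawn, each
rater's scores are averaged per combination and snapped back to the
half-step grid, and weighted kappa is computed over the resulting
mean-pairs.  Overlapping combinations are not independent observations, so
the standard error reported for the aggregate kappa is descriptive only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateTableError, EmptyInputError, InvalidParameterError
from .stages_model import GRID, level_index, snap_to_grid

#: z multiplier for the 95% confidence interval.
CI_Z = 1.96


@dataclass
class CrossTab:
    """A k x k ordinal contingency table of paired scores.

    Rows index rater A, columns rater B.  The full fixed 12-level grid is
    always present, including empty categories — kappa is unaffected, but
    marginal reports stay on the complete scale.
    """

    counts: np.ndarray
    grid: tuple[float, ...] = GRID

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.grid)
        if self.counts.shape != (k, k):
            raise InvalidParameterError(
                f"counts must be {k}x{k} for a {k}-level grid, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.grid)


@dataclass(frozen=True)
class AgreementResult:
    """Kappa with its asymptotic standard error and 95% CI."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def build_crosstab(pairs: Sequence[tuple[float, float]]) -> CrossTab:
    """Cross-tabulate (rater A, rater B) level pairs on the full 12-level
    grid.  Off-grid values raise :class:`InvalidLevelError`."""
    k = len(GRID)
    counts = np.zeros((k, k), dtype=int)
    for a, b in pairs:
        counts[level_index(a), level_index(b)] += 1
    return CrossTab(counts=counts)


def quadratic_weights(k: int) -> np.ndarray:
    """k x k quadratic disagreement weights, w_ij = (i-j)^2 / (k-1)^2.

    Zero on the diagonal, 1 at the opposite corners.
    """
    if not isinstance(k, int) or k < 2:
        raise InvalidParameterError(f"k must be an integer >= 2, got {k!r}")
    idx = np.arange(k)
    return (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def weighted_kappa(tab: CrossTab, weights: np.ndarray | None = None) -> AgreementResult:
    """Quadratic-weighted Cohen's kappa for a cross-tabulation.

    ``weights`` may override the disagreement weight matrix (same shape as
    the table); kappa is invariant to rescaling it by a positive constant.
    The standard error is the Fleiss-Cohen-Everitt asymptotic (non-null)
    form, evaluated with agreement weights v = 1 - w/max(w).
    """
    counts = np.asarray(tab.counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise DegenerateTableError("need at least 2 paired observations")
    if weights is None:
        w = quadratic_weights(tab.k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != counts.shape:
            raise InvalidParameterError("weights shape must match the table")
        if (w < 0).any() or w.max() <= 0:
            raise InvalidParameterError("disagreement weights must be >= 0 with a positive max")
    # Normalize so the largest disagreement weighs 1; kappa is invariant,
    # and the agreement weights v = 1 - w stay in [0, 1] for the variance.
    w = w / w.max()

    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    obs_dis = float((w * p).sum())
    exp_dis = float((w * expected).sum())
    if exp_dis == 0.0:
        raise DegenerateTableError(
            "zero expected disagreement (all mass in one category); kappa undefined"
        )
    kappa = 1.0 - obs_dis / exp_dis

    # Fleiss, Cohen & Everitt (1969) non-null variance, agreement-weight form.
    v = 1.0 - w
    po = float((v * p).sum())
    pe = float((v * expected).sum())
    vbar_row = (v * col[None, :]).sum(axis=1)   # E[v | rater A category]
    vbar_col = (v * row[:, None]).sum(axis=0)   # E[v | rater B category]
    term = (v - (vbar_row[:, None] + vbar_col[None, :]) * (1.0 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(kappa - CI_Z * se),
        ci_high=float(kappa + CI_Z * se),
        n=int(n),
    )


def aggregate_agreement(pairs: Sequence[tuple[float, float]],
                        combo_size: int = 10,
                        n_combos: int = 5000,
                        seed: int = 0) -> AgreementResult:
    """Weighted kappa between snapped mean scores of random combinations.

    Draws ``n_combos`` random combinations of ``combo_size`` pairs (without
    replacement within a combination; combinations themselves may repeat),
    averages each rater's scores per combination, snaps both means to the
    half-step grid, and computes quadratic-weighted kappa over the snapped
    mean-pairs.  The reported se treats the combinations as independent,
    which overlapping combinations violate — it is descriptive only.
    """
    if len(pairs) == 0:
        raise EmptyInputError("no pairs to resample")
    if not 1 <= combo_size <= len(pairs):
        raise InvalidParameterError(
            f"combo_size must lie in [1, {len(pairs)}], got {combo_size}"
        )
    if n_combos < 1:
        raise InvalidParameterError("n_combos must be >= 1")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    for v in np.concatenate([a, b]):
        level_index(v)  # validate on-grid
    rng = np.random.default_rng(seed)
    idx = np.array([rng.choice(len(pairs), size=combo_size, replace=False)
                    for _ in range(n_combos)])
    mean_a = a[idx].mean(axis=1)
    mean_b = b[idx].mean(axis=1)
    snapped = [(snap_to_grid(x), snap_to_grid(y)) for x, y in zip(mean_a, mean_b)]
    return weighted_kappa(build_crosstab(snapped))
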