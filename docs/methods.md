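# Methods

## The scoring model

A sentence-completion response is placed on the STAGES grid — 12 levels
from 1.0 to 6.5 in half steps — by three categorical judgements: the tier
of object awareness (Concrete / Subtle / MetAware), the person perspective
(Individual / Collective) and the agency orientation (Passive / Active).
The level is the closed form `2·(q1−1) + q2 + 0.5·(q3−1)`: each tier owns a
block of four consecutive levels, the collective focus adds a whole step
within the block, the active orientation a half step. This is the unique
order-consistent assignment of the 12 = 3×2×2 possible triples onto the 12
levels, and it is consistent with every half-step score in the
bundled validation set. The richer four-way agency taxonomy sometimes
described for STAGES (receptive / active / reciprocal / interpenetrative)
is out of scope: the implemented classification prompt is binary
Passive/Active, so the model here is binary too.

## Backends and determinism

The classifier contract is a single method `(sentence, question_id) →
category code`. The remote backend renders the protocol's verbatim prompt
templates, sends them through a caller-supplied transport callable, parses
the reply (first in-range digit, then case-insensitive category name) and
appends every exchange to a JSON-lines cache keyed by (model, question,
sentence, temperature, top_p). Temperature defaults to 0 and top-p to a
near-greedy 0.01; remote APIs are still not bit-deterministic, which is why
the *cache*, not the sampler settings, is the reproducibility boundary: a
populated cache replays a scoring run with zero network calls. Unparsable
replies are retried up to a configured count (default 2), then the run is
dropped with a logged warning; a sentence fails only if every run fails.

The mock backend is a pure keyword-rule classifier transcribed from the
prompts' own criteria and example lists: MetAware markers (awareness /
construct / reality / perception …) take precedence over Subtle markers
(values / balance / uncertainty …) over the Concrete default; Q2 fires on
the prompt's collective word list, defaulting to Individual; Q3 fires on an
agentive main-verb list, defaulting to Passive. It exists to make the whole
pipeline testable offline, and every example sentence the prompts list is a
unit test pinning its behaviour.

## Median-of-runs stabilization

A sentence is classified `n_runs` times (default 10) and scored by the
median of the per-run levels. All medians are **lower medians** — the
element at position ⌈n/2⌉ of the sorted list — because an interpolated
even-n median (e.g. 3.25) is not an attainable level. Per-question lower
medians are recorded alongside since both series feed the run-count
calibration. The sentence score is the median of per-run *levels*, not the
level of per-question medians; the two can differ and both are exposed.

The run-count calibration regresses the median outcome on the number of
runs over windows [start, 30] for starts {3, 5, 10, 15, 20} and reports the
OLS slope and intercept per window (via `scipy.stats.linregress`). The
stabilization point is formalized here as the smallest window start from
which *every* window's |slope| stays within a tolerance (default 0.005
levels per run); when no start qualifies the result is flagged unstable
rather than silently reporting a number. This formalization is deliberate:
published slope tables for this protocol are not monotone near zero (a late
window can bounce back above any reasonable tolerance), so "the curve
flattened" needs an explicit, checkable rule.

## Respondent aggregation and the minimum-item analysis

Respondents are positioned by the arithmetic mean of their sentence scores,
snapped to the grid. Snapping is half-up on twice the value (3.75 → 4.0)
and clamps to [1.0, 6.5]; half-up is a documented choice where the
convention was unspecified. The accepted minimum is 5 sentences, 10
recommended — the subsample analysis motivates both: for each subsample
size it draws random combinations (default 5,000), measures |combination
mean − full-set mean|, and reports the mean and population standard
deviation of those absolute differences. Combinations are drawn without
replacement within a combination; distinct draws may repeat across
combinations, which is unavoidable whenever C(N, k) < 5,000 and harmless
otherwise. Population (divide-by-n) standard deviation is used so results
are comparable across sizes.

## Agreement statistics

Expert-vs-protocol agreement uses Cohen's weighted kappa with quadratic
disagreement weights `w_ij = (i−j)²/(k−1)²` on the full fixed 12-category
cross-tabulation (empty categories included — kappa is provably invariant
to them, and to any positive rescaling of the weights, but the marginal
layout stays on the complete scale). The standard error is the asymptotic
non-null variance of Fleiss, Cohen & Everitt (1969) in its agreement-weight
form; on the bundled 58-pair validation table it reproduces the published
kappa 0.77987, se 0.05491 and CI (0.67225, 0.88749) to all printed
decimals, which is what fixed this variant among the several in the
literature. The CI multiplier is 1.96 throughout.

Aggregate (group-level) agreement draws `n_combos` random combinations of
`combo_size` sentence pairs, averages each rater's scores per combination,
snaps both means to the grid and computes weighted kappa over the snapped
mean-pairs. The resampled pairs are treated as independent observations,
so the aggregate se is descriptive only — overlapping combinations violate
independence.

### A known discrepancy

For 10-sentence combinations from the bundled validation set this
procedure yields κ ≈ 0.55 for any seed, not the published 0.7052. The gap
is structural, not Monte-Carlo: quadratic-weighted kappa on paired means is
algebraically Lin's concordance correlation,
`2·Cov / (Var_A + Var_B + (mean_A − mean_B)²)`, and the two raters' full-set
means differ by 0.29 levels (3.71 vs. 3.41). Averaging shrinks the random
disagreement but leaves this offset intact, so the chance-corrected
agreement of means is capped near 0.55. The published value is instead
consistent, within Monte-Carlo error, with the *Pearson correlation* of the
snapped means (≈ 0.705 at this combination size), a statistic that ignores
the mean offset. This package computes the weighted kappa the procedure
states; the aggregate-agreement acceptance check against 0.7052 therefore
fails by design, and the number it does produce (~0.55) is the faithful
one.

## Synthetic data

Two generators support the test suite and have no other ambitions.

* **Copy-mixture paired ratings**: rater A draws from a marginal over the
  grid; rater B copies A with probability `a`, else redraws independently
  from the same marginal. The population quadratic-weighted kappa equals
  `a` for any marginal (observed disagreement is (1−a) × chance
  disagreement), so estimator recovery `|κ̂ − a|` is an analytic property
  test with no external data. Defaults: uniform marginal, n as requested by
  the test (property tests use n = 5,000, where the binomial noise keeps
  κ̂ within ±0.03 of `a`).
* **Marker-bearing sentences**: subject / verb / object templates are
  assembled from the mock backend's own marker vocabulary so the mock
  pipeline recovers the intended (tier, person, agency) triple exactly.
  These sentences are a deterministic harness for the pipeline and are
  explicitly *not* a simulation of human SCT responses — passing the
  round-trip test shows the pipeline is wired correctly, not that the
  keyword rules score real prose like an expert.

## Numerical and design choices

* Lower medians everywhere a median of grid values is needed (attainable
  values; permutation-invariant).
* Half-up snapping of means; out-of-range reals are clamped, not rejected
  (means of grid values cannot leave the grid range, so clamping only
  defends against caller error).
* Degenerate agreement tables (n < 2, all mass in one category, zero
  expected disagreement) raise rather than returning NaN.
* Seeds: every stochastic routine takes an explicit seed and uses
  `numpy.random.default_rng`; batch scoring derives per-sentence seeds so
  results do not depend on batch order.
* Problem sizes in the test suite (5,000 resampled combinations, 5,000
  mixture pairs, 300–1,000 generated sentences) match the validation
  procedure's own scale while keeping the whole suite in seconds.

## Limitations

* The remote backend ships without any vendor SDK; callers supply a
  transport callable, and recorded caches are the supported path to exact
  reproduction.
* The bundled validation set is small (58 sentences) and its STAGES scores
  were produced by the original protocol run, not recomputed here; the
  keyword mock cannot and should not reproduce them.
* The aggregate-agreement se treats overlapping combinations as
  independent; use it descriptively.
* Minimum-item recommendations derived from one dataset do not transfer
  automatically to populations with different score dispersion.
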