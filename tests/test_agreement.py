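"""Cross-tabulation and quadratic-weighted kappa with asymptotic SE."""

import numpy as np
import pytest

from stagescore import (
    GRID,
    CrossTab,
    aggregate_agreement,
    build_crosstab,
    quadratic_weights,
    weighted_kappa,
)
from stagescore.errors import (
    DegenerateTableError,
    EmptyInputError,
    InvalidLevelError,
    InvalidParameterError,
)


class TestBuildCrosstab:
    def test_reproduces_the_validation_crosstab_cell_for_cell(
            self, table3_pairs, table4_expected):
        tab = build_crosstab(table3_pairs)
        assert np.array_equal(tab.counts, table4_expected)
        assert tab.n == 58

    def test_spot_cells(self, table3_pairs):
        tab = build_crosstab(table3_pairs)
        i4 = GRID.index(4.0)
        assert tab.counts[i4, i4] == 14
        assert tab.counts[i4].sum() == 26        # MAP-4 row total
        assert tab.counts[:, i4].sum() == 20     # STAGES-4 column total

    def test_empty_pairs(self):
        tab = build_crosstab([])
        assert tab.n == 0
        assert not tab.counts.any()

    def test_identical_pairs_fill_the_diagonal(self):
        tab = build_crosstab([(lvl, lvl) for lvl in GRID])
        assert np.array_equal(tab.counts, np.eye(12, dtype=int))

    def test_off_grid_values_rejected(self):
        with pytest.raises(InvalidLevelError):
            build_crosstab([(4.2, 4.0)])


class TestQuadraticWeights:
    def test_two_categories(self):
        assert np.array_equal(quadratic_weights(2), [[0, 1], [1, 0]])

    def test_twelve_category_corners_and_diagonal(self):
        w = quadratic_weights(12)
        assert w[0, 11] == 1.0 and w[11, 0] == 1.0
        assert np.all(np.diag(w) == 0)

    def test_symmetry(self):
        w = quadratic_weights(7)
        assert np.array_equal(w, w.T)

    @pytest.mark.parametrize("k", [0, 1, -3])
    def test_small_k_rejected(self, k):
        with pytest.raises(InvalidParameterError):
            quadratic_weights(k)


def product_table(row_marg, col_marg, scale=1):
    """Counts proportional to the outer product of the marginals (chance)."""
    return np.outer(row_marg, col_marg) * scale


class TestWeightedKappa:
    def test_validation_table_statistics(self, table3_pairs):
        result = weighted_kappa(build_crosstab(table3_pairs))
        assert result.kappa == pytest.approx(0.77987, abs=5e-5)
        assert result.se == pytest.approx(0.05491, abs=5e-4)
        assert result.ci_low == pytest.approx(result.kappa - 1.96 * result.se)
        assert result.ci_high == pytest.approx(result.kappa + 1.96 * result.se)
        assert result.n == 58

    def test_perfect_agreement(self):
        tab = build_crosstab([(lvl, lvl) for lvl in GRID for _ in range(3)])
        assert weighted_kappa(tab).kappa == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        counts = np.zeros((12, 12))
        counts[2:6, 2:6] = product_table([1, 2, 3, 4], [4, 3, 2, 1], scale=10)
        assert weighted_kappa(CrossTab(counts=counts)).kappa == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_sklearn_on_random_pairs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(17)
        a_idx = rng.integers(0, 12, size=400)
        b_idx = np.clip(a_idx + rng.integers(-2, 3, size=400), 0, 11)
        pairs = [(GRID[i], GRID[j]) for i, j in zip(a_idx, b_idx)]
        ours = weighted_kappa(build_crosstab(pairs)).kappa
        theirs = sklearn_metrics.cohen_kappa_score(
            a_idx, b_idx, labels=list(range(12)), weights="quadratic")
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_to_weight_rescaling(self, table3_pairs):
        tab = build_crosstab(table3_pairs)
        base = weighted_kappa(tab)
        idx = np.arange(12)
        unnormalized = (idx[:, None] - idx[None, :]) ** 2.0  # x121 larger
        rescaled = weighted_kappa(tab, weights=unnormalized)
        assert rescaled.kappa == pytest.approx(base.kappa, abs=1e-12)
        assert rescaled.se == pytest.approx(base.se, abs=1e-12)

    def test_invariant_to_empty_category_padding(self):
        # same pairs expressed on a 5-level grid and embedded in the 12-level
        # grid: kappa and se must agree because spacing is preserved
        rng = np.random.default_rng(23)
        small_grid = GRID[:5]
        a = rng.integers(0, 5, size=200)
        b = np.clip(a + rng.integers(-1, 2, size=200), 0, 4)
        counts5 = np.zeros((5, 5))
        for i, j in zip(a, b):
            counts5[i, j] += 1
        small = weighted_kappa(CrossTab(counts=counts5, grid=small_grid))
        padded = weighted_kappa(
            build_crosstab([(small_grid[i], small_grid[j]) for i, j in zip(a, b)]))
        assert padded.kappa == pytest.approx(small.kappa, abs=1e-12)
        assert padded.se == pytest.approx(small.se, abs=1e-12)

    def test_single_cell_table_is_degenerate(self):
        counts = np.zeros((12, 12))
        counts[3, 3] = 50
        with pytest.raises(DegenerateTableError):
            weighted_kappa(CrossTab(counts=counts))

    def test_fewer_than_two_observations(self):
        with pytest.raises(DegenerateTableError):
            weighted_kappa(build_crosstab([(3.0, 3.5)]))


class TestAggregateAgreement:
    def test_perfect_agreement_survives_aggregation(self):
        pairs = [(lvl, lvl) for lvl in GRID for _ in range(3)]
        result = aggregate_agreement(pairs, combo_size=5, n_combos=300, seed=0)
        assert result.kappa == pytest.approx(1.0)

    def test_single_item_combinations_approach_the_per_sentence_kappa(
            self, table3_pairs):
        per_sentence = weighted_kappa(build_crosstab(table3_pairs)).kappa
        resampled = aggregate_agreement(table3_pairs, combo_size=1,
                                        n_combos=20000, seed=4).kappa
        assert resampled == pytest.approx(per_sentence, abs=0.03)

    def test_reproducible_for_a_fixed_seed(self, table3_pairs):
        a = aggregate_agreement(table3_pairs, combo_size=10, n_combos=500, seed=9)
        b = aggregate_agreement(table3_pairs, combo_size=10, n_combos=500, seed=9)
        assert a.kappa == b.kappa and a.se == b.se

    @pytest.mark.parametrize("kwargs", [
        {"combo_size": 0}, {"combo_size": 59}, {"n_combos": 0},
    ])
    def test_invalid_parameters(self, table3_pairs, kwargs):
        with pytest.raises(InvalidParameterError):
            aggregate_agreement(table3_pairs, **{"combo_size": 10, "n_combos": 10, **kwargs})

    def test_empty_pairs(self):
        with pytest.raises(EmptyInputError):
            aggregate_agreement([], combo_size=1, n_combos=10)
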