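import numpy as np
import pytest
from scipy import stats as sps

from sirna_access.stats import (
    RankDeficiencyError,
    SeparationError,
    chi_square_rxc,
    fisher_exact_2x2,
    logistic_multivariable,
    logistic_univariable,
    one_sample_proportion,
    two_group_compare,
)

from oracles import fisher_p_enum, logistic_grid_mle, mann_whitney_u_brute


class TestLogisticUnivariable:
    def test_balanced_design_gives_or_of_one(self):
        # identical x values in both classes: no association by construction
        y = [0, 1] * 10
        x = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0, 5.0, 5.0] * 2
        res = logistic_univariable(y, x)
        assert res.odds_ratio[0] == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low[0] < 1.0 < res.ci_high[0]

    def test_matches_grid_search_mle(self):
        y = [0, 0, 1, 0, 1, 1, 0, 1, 1, 0]
        x = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        b0, b1 = logistic_grid_mle(y, x)
        res = logistic_univariable(y, x)
        assert res.coef[0] == pytest.approx(b1, abs=1e-4)

    def test_separation_detected(self):
        y = [0] * 6 + [1] * 6
        x = list(range(6)) + list(range(10, 16))
        with pytest.raises(SeparationError):
            logistic_univariable(y, x)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_univariable([0, 1] * 5, [3.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            logistic_univariable([0, 1, 0, 1], [1, 2, 3, 4])

    def test_robust_and_classical_cis_differ(self, rng):
        x = rng.normal(size=80)
        y = (rng.random(80) < 0.5).astype(int)
        robust = logistic_univariable(y, x, robust=True)
        classical = logistic_univariable(y, x, robust=False)
        assert robust.odds_ratio == classical.odds_ratio
        assert robust.ci_low != classical.ci_low


class TestLogisticMultivariable:
    def test_recovers_informative_column_among_noise(self, rng):
        n, beta = 4000, 0.8
        X = rng.normal(size=(n, 8))
        eta = beta * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = logistic_multivariable(y, X)
        assert res.coef[0] == pytest.approx(beta, abs=0.15)
        assert all(abs(c) < 0.15 for c in res.coef[1:])

    def test_duplicated_column_reported(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(RankDeficiencyError, match="x3"):
            logistic_multivariable(y, X, names=["x1", "x2", "x3"])

    def test_too_few_observations_rejected(self):
        X = np.arange(72, dtype=float).reshape(9, 8)
        y = [0, 1] * 4 + [0]
        with pytest.raises(ValueError, match="n > predictors"):
            logistic_multivariable(y, X)


class TestTwoGroupCompare:
    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = two_group_compare(a, a, force_test="t")
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_identical_groups_mann_whitney_u(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = two_group_compare(a, a, force_test="mann_whitney")
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)

    def test_shifted_groups_significant(self, rng):
        a = rng.normal(size=30)
        b = a + 100.0
        res = two_group_compare(a, b)
        assert res.p_value < 1e-6

    def test_u_statistic_equals_pairwise_wins(self, rng):
        for _ in range(25):
            a = rng.integers(0, 6, size=5).astype(float)
            b = rng.integers(0, 6, size=5).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            res = two_group_compare(a, b, force_test="mann_whitney")
            assert res.statistic == pytest.approx(mann_whitney_u_brute(a, b))

    def test_degenerate_equal_constant_groups(self):
        res = two_group_compare([2.0] * 5, [2.0] * 5)
        assert res.p_value == 1.0

    def test_non_normal_data_routed_to_mann_whitney(self, rng):
        a = rng.lognormal(0, 2, size=50) ** 2
        b = rng.lognormal(0, 2, size=50) ** 2
        res = two_group_compare(a, b)
        assert res.test == "mann_whitney"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            two_group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFisherExact:
    def test_hand_enumerated_example(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_identical_rows_give_one(self):
        assert fisher_exact_2x2([[4, 7], [4, 7]]) == pytest.approx(1.0)

    def test_perfect_concordance_tail(self):
        from math import comb

        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / comb(20, 10))

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_agrees_with_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 8, size=(2, 2))
            if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_p_enum(t), rel=1e-9)


class TestChiSquare:
    def test_identical_rows(self):
        stat, p = chi_square_rxc([[5, 10, 5], [5, 10, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        table = np.array([[10, 20], [20, 10]])
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        with pytest.warns(UserWarning) if (expected < 5).any() else _nullcontext():
            stat, _ = chi_square_rxc(table)
        assert stat == pytest.approx(by_hand)

    def test_scaling_counts_scales_statistic(self):
        t = np.array([[8, 12], [14, 6]])
        s1, _ = chi_square_rxc(t)
        s3, _ = chi_square_rxc(3 * t)
        assert s3 == pytest.approx(3 * s1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chi_square_rxc([[0, 0], [3, 4]])

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            chi_square_rxc([[1, 9], [2, 8]])


from contextlib import nullcontext as _nullcontext


class TestOneSampleProportion:
    def test_observed_equals_expected_is_maximal(self):
        assert one_sample_proportion(10, 20, 0.5) == pytest.approx(1.0)

    def test_extreme_tail(self):
        assert one_sample_proportion(0, 20, 0.5) == pytest.approx(2 * 2.0 ** -20)

    def test_reference_null_proportion_runs(self):
        p = one_sample_proportion(129, 150, 0.517)
        assert 0.0 < p < 1e-6  # 86% observed vs 51.7% expected is far off

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_proportion(21, 20, 0.5)
        with pytest.raises(ValueError):
            one_sample_proportion(5, 20, 1.0)


class TestCompositionalPredictors:
    def test_counts_partitioning_a_fixed_total_need_no_intercept(self, rng):
        # per-element base counts of a fixed-length site sum to a constant,
        # so the intercept model is singular but the intercept-free fit works
        n = 300
        X = rng.multinomial(19, [0.2, 0.1, 0.1, 0.1, 0.2, 0.1, 0.1, 0.1], size=n)
        X = X.astype(float)
        y = (rng.random(n) < 0.5).astype(int)
        with pytest.raises(RankDeficiencyError):
            logistic_multivariable(y, X)
        res = logistic_multivariable(y, X, intercept=False)
        assert len(res.odds_ratio) == 8
        assert all(lo <= o <= hi for lo, o, hi in
                   zip(res.ci_low, res.odds_ratio, res.ci_high))
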