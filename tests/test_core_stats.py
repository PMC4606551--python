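"""Null-distribution machinery: support bound, confidence quantile, back-solve."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dar import (
    RuleCounts,
    back_solve_joint_probability,
    confidence_distribution,
    critical_value_table,
    estimate_item_probabilities,
    minimum_confidence,
    minimum_support,
    simulate_independent_baskets,
    z_quantile,
)


class TestRuleCounts:
    def test_invariant_violations_raise(self):
        with pytest.raises(ValueError):
            RuleCounts(n=0, n_A=0, n_B=0, n_AB=0)
        with pytest.raises(ValueError):
            RuleCounts(n=10, n_A=3, n_B=5, n_AB=4)  # n_AB > n_A
        with pytest.raises(ValueError):
            RuleCounts(n=10, n_A=11, n_B=5, n_AB=0)
        with pytest.raises(ValueError):
            RuleCounts(n=10, n_A=-1, n_B=5, n_AB=0)


class TestEstimators:
    def test_marginals_from_counts(self):
        p = estimate_item_probabilities(RuleCounts(n=1000, n_A=300, n_B=700, n_AB=210))
        assert p.p1 == pytest.approx(0.3)
        assert p.p2 == pytest.approx(0.7)
        assert p.p12 == pytest.approx(0.21)
        assert p.p2_given_1 == pytest.approx(0.7)

    def test_empty_antecedent_has_undefined_conditional(self):
        p = estimate_item_probabilities(RuleCounts(n=10, n_A=0, n_B=5, n_AB=0))
        assert p.p1 == 0.0
        assert p.p2_given_1 is None

    def test_saturated_counts(self):
        p = estimate_item_probabilities(RuleCounts(n=10, n_A=10, n_B=10, n_AB=10))
        assert (p.p1, p.p2, p.p12, p.p2_given_1) == (1.0, 1.0, 1.0, 1.0)


class TestMinimumSupport:
    @pytest.mark.parametrize(
        "p1, p2, n, alpha, expected, dp",
        [
            (0.3, 0.7, 1000, 0.05, 0.2312, 4),
            (0.625, 0.5, 16, 0.05, 0.5031, 4),
            (0.625, 0.5, 16, 0.10, 0.461, 3),
        ],
    )
    def test_published_values(self, p1, p2, n, alpha, expected, dp):
        assert round(minimum_support(p1, p2, n, alpha), dp) == expected

    def test_alpha_half_gives_the_joint_probability(self):
        for p1, p2, n in [(0.3, 0.7, 50), (0.9, 0.2, 7), (0.5, 0.5, 1000)]:
            assert minimum_support(p1, p2, n, 0.5) == pytest.approx(p1 * p2)

    @pytest.mark.parametrize("p1,p2", [(0.0, 0.7), (0.3, 0.0), (1.0, 1.0)])
    def test_degenerate_joint_probability_returns_it_exactly(self, p1, p2):
        assert minimum_support(p1, p2, 20, 0.05) == p1 * p2

    def test_exceeds_joint_probability_and_shrinks_with_n(self):
        small = minimum_support(0.4, 0.5, 50, 0.05)
        big = minimum_support(0.4, 0.5, 500000, 0.05)
        assert small > 0.2 and big > 0.2
        assert big - 0.2 < small - 0.2
        assert big == pytest.approx(0.2, abs=1e-3)

    def test_exact_binomial_option_close_to_normal(self):
        approx = minimum_support(0.3, 0.7, 1000, 0.05)
        exact = minimum_support(0.3, 0.7, 1000, 0.05, exact_binomial=True)
        assert abs(exact - approx) < 0.005

    def test_invalid_alpha_raises(self):
        for alpha in (0.0, 0.7, -0.1, 1.0):
            with pytest.raises(ValueError):
                minimum_support(0.3, 0.7, 100, alpha)

    def test_tabled_z_value(self):
        assert z_quantile(0.05, rounded=True) == 1.645
        assert z_quantile(0.05) == pytest.approx(1.6449, abs=1e-4)
        assert z_quantile(0.5) == pytest.approx(0.0, abs=1e-12)


class TestConfidenceDistribution:
    def test_degenerate_consequent_is_point_mass_at_zero(self):
        dist = confidence_distribution(20, 0.4, 0.0)
        assert len(dist.values) == 1
        assert dist.values[0] == 0.0
        assert dist.pmf[0] == pytest.approx(1.0)

    def test_zero_antecedent_probability_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            confidence_distribution(20, 0.0, 0.5)

    @pytest.mark.parametrize("n,p1,p2", [(30, 0.4, 0.6), (50, 0.1, 0.3), (16, 0.625, 0.5)])
    def test_pmf_normalised_and_values_increasing(self, n, p1, p2):
        dist = confidence_distribution(n, p1, p2)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.values) > 0)
        assert dist.values[0] >= 0.0 and dist.values[-1] <= 1.0

    @pytest.mark.parametrize("p1", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("p2", [0.1, 0.3, 0.5])
    def test_reflection_symmetry_in_p2(self, p1, p2):
        """PMF at consequent probability p maps atom-by-atom onto 1-p under c -> 1-c."""
        d1 = confidence_distribution(50, p1, p2)
        d2 = confidence_distribution(50, p1, 1.0 - p2)
        np.testing.assert_allclose(d1.values, np.sort(1.0 - d2.values), atol=1e-12)
        np.testing.assert_allclose(d1.pmf, d2.pmf[::-1], atol=1e-12)

    def test_matches_monte_carlo_ratio_distribution(self):
        """Exact PMF agrees with simulated n_AB/n_A over many basket sets."""
        n, p1, p2, reps = 30, 0.4, 0.6, 200_000
        rng = np.random.default_rng(20240901)
        a = rng.random((reps, n)) < p1
        b = rng.random((reps, n)) < p2
        n_a = a.sum(axis=1)
        keep = n_a > 0
        conf = (a & b).sum(axis=1)[keep] / n_a[keep]
        dist = confidence_distribution(n, p1, p2)
        for q in [0.2, 0.4, 0.5, 0.6, 0.8]:
            exact = float(np.interp(q, dist.values, dist.cdf))
            emp = float(np.mean(conf <= q))
            assert abs(emp - exact) < 3 * math.sqrt(0.25 / reps) + 1e-9, q


class TestMinimumConfidence:
    @pytest.mark.parametrize(
        "n, p1, p2, alpha, expected",
        [
            (1000, 0.3, 0.7, 0.05, 0.7425),
            (1000, 0.1, 0.1, 0.20, 0.1245),
            (1000, 0.1, 0.9, 0.01, 0.9635),
        ],
    )
    def test_reference_grid_values(self, n, p1, p2, alpha, expected):
        assert minimum_confidence(n, p1, p2, alpha) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "alpha, expected",
        [(0.05, (10 / 13 + 7 / 9) / 2), (0.10, (7 / 10 + 5 / 7) / 2)],
    )
    def test_exact_convention_small_sample(self, alpha, expected):
        """At n=16 the exact convention lands between consecutive achievable ratios."""
        got = minimum_confidence(16, 0.625, 0.5, alpha, convention="exact")
        assert got == pytest.approx(expected, abs=1e-12)
        assert round(got, 4) in (0.7735, 0.7071)

    def test_degenerate_consequent(self):
        assert minimum_confidence(100, 0.3, 0.0, 0.05) == 0.0
        assert minimum_confidence(100, 0.3, 1.0, 0.05) == 1.0

    def test_monotone_in_marginals_and_level(self):
        grid = [0.2, 0.4, 0.6, 0.8]
        for conv in ("grid", "exact"):
            for p2 in (0.3, 0.6):
                vals = [minimum_confidence(60, p1, p2, 0.05, convention=conv)
                        for p1 in grid]
                assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
            for p1 in (0.3, 0.6):
                vals = [minimum_confidence(60, p1, p2, 0.05, convention=conv)
                        for p2 in grid]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
                vals = [minimum_confidence(60, p1, 0.5, a, convention=conv)
                        for a in (0.2, 0.1, 0.05, 0.01)]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_grid_matches_normal_approximation_for_large_n(self):
        n, p1, p2, alpha = 100_000, 0.3, 0.5, 0.05
        got = minimum_confidence(n, p1, p2, alpha)
        approx = p2 + z_quantile(alpha) * math.sqrt(p2 * (1 - p2) / (n * p1))
        assert abs(got - approx) < 0.002

    def test_quantiles_calibrated_against_simulation(self):
        """P(C > c_min) <= alpha for simulated independent baskets."""
        n, p1, p2, alpha, reps = 50, 0.3, 0.5, 0.05, 50_000
        rng = np.random.default_rng(7)
        a = rng.random((reps, n)) < p1
        b = rng.random((reps, n)) < p2
        n_a = a.sum(axis=1)
        keep = n_a > 0
        conf = (a & b).sum(axis=1)[keep] / n_a[keep]
        c_exact = minimum_confidence(n, p1, p2, alpha, convention="exact")
        exceed = float(np.mean(conf > c_exact))
        assert exceed <= alpha + 3 * math.sqrt(alpha / reps)
        # the grid reporting convention cuts within the same achievable-ratio
        # gap as the exact threshold, up to one grid step
        c_grid = minimum_confidence(n, p1, p2, alpha, convention="grid")
        dist = confidence_distribution(n, p1, p2)
        i = int(np.searchsorted(dist.cdf, 1 - alpha - 1e-12))
        assert dist.values[i] - 1e-3 <= c_grid <= dist.values[i + 1] + 1e-3

    def test_unknown_convention_raises(self):
        with pytest.raises(ValueError, match="convention"):
            minimum_confidence(50, 0.3, 0.5, 0.05, convention="banana")


class TestCriticalValueTable:
    def test_layout_and_spot_values(self):
        tab = critical_value_table(1000, [0.1, 0.5], [0.1, 0.9], [0.80, 0.99])
        assert tab.shape == (4, 2)
        assert tab.index.names == ["p2", "level"]
        assert tab.loc[(0.9, 0.99), 0.1] == pytest.approx(0.9635, abs=1e-9)

    def test_zero_consequent_column_is_zero(self):
        tab = critical_value_table(200, [0.3], [0.0], [0.9, 0.95])
        assert (tab.to_numpy() == 0.0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            critical_value_table(100, [], [0.5], [0.95])


class TestBackSolve:
    def test_round_trip_of_worked_example(self):
        p_star = back_solve_joint_probability(1000, 0.2312, 0.05)
        assert p_star == pytest.approx(0.2101, abs=5e-4)
        z = z_quantile(0.05)
        s = p_star + z * math.sqrt(p_star * (1 - p_star) / 1000)
        assert s == pytest.approx(0.2312, abs=1e-9)

    def test_alpha_half_collapses_to_s(self):
        assert back_solve_joint_probability(100, 0.3, 0.5) == pytest.approx(0.3)

    def test_monotone_in_s(self):
        assert back_solve_joint_probability(100, 0.4, 0.05) > back_solve_joint_probability(
            100, 0.3, 0.05
        )

    @given(
        n=st.integers(10, 100_000),
        s=st.floats(0.01, 0.95),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.25, 0.5]),
    )
    def test_round_trip_property(self, n, s, alpha):
        """minimum_support at the root recovers s to within 1e-9."""
        p_star = back_solve_joint_probability(n, s, alpha)
        assert 0.0 < p_star <= s + 1e-12
        z = z_quantile(alpha)
        recovered = p_star + z * math.sqrt(p_star * (1 - p_star) / n)
        assert abs(recovered - s) < 1e-9

    def test_invalid_support_raises(self):
        for s in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                back_solve_joint_probability(100, s, 0.05)
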