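"""Difference curves, AUC summarization and permutation testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from genconn.inference import (
    InferenceError,
    auc,
    group_difference_curve,
    permutation_test,
    slope_difference_curve,
)

DENSITIES = np.round(np.arange(1, 31) / 100, 2)


class TestGroupDifference:
    def test_identical_groups_zero_curve(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((4, 30))
        values = np.vstack([block, block])
        risk = np.array([True] * 4 + [False] * 4)
        assert np.allclose(group_difference_curve(values, risk), 0.0)

    def test_location_shift_constant_curve(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((10, 30))
        risk = np.arange(10) < 5
        shifted = values.copy()
        shifted[risk] += 0.1
        diff = group_difference_curve(shifted, risk) - group_difference_curve(values, risk)
        assert np.allclose(diff, 0.1, atol=1e-12)

    def test_toy_table_hand_computation(self):
        values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 10.0], [7.0, 0.0]])
        risk = np.array([True, True, False, False])
        assert np.allclose(group_difference_curve(values, risk), [2.0 - 6.0, 3.0 - 5.0])

    def test_empty_group_rejected(self):
        with pytest.raises(InferenceError):
            group_difference_curve(np.zeros((3, 5)), np.array([True, True, True]))


class TestSlopeDifference:
    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(135, 19, 8)
        values = rng.standard_normal((8, 1))
        risk = np.arange(8) < 4
        d = slope_difference_curve(values, x, risk)[0]
        expected = oracles.ols_slope(x[risk], values[risk, 0]) - oracles.ols_slope(
            x[~risk], values[~risk, 0]
        )
        assert d == pytest.approx(expected, rel=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(135, 19, 12)
        y = rng.standard_normal(12)
        risk = np.arange(12) < 6
        d = slope_difference_curve(y[:, None], x, risk)[0]
        s1 = sm.OLS(y[risk], sm.add_constant(x[risk])).fit().params[1]
        s0 = sm.OLS(y[~risk], sm.add_constant(x[~risk])).fit().params[1]
        assert d == pytest.approx(s1 - s0, rel=1e-10)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(135.5, 18.9, n)
        risk = np.arange(n) < n // 2
        b = -0.02
        y = np.where(risk, b * x, 0.0) + 0.1 * rng.standard_normal(n)
        d = slope_difference_curve(y[:, None], x, risk)[0]
        assert d == pytest.approx(b, abs=5e-3)

    def test_null_construction_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(135.5, 18.9, n)
        y = 0.01 * x + rng.standard_normal(n)  # same slope both groups
        risk = np.arange(n) < n // 2
        d = slope_difference_curve(y[:, None], x, risk)[0]
        se = 2 * 1.0 / (18.9 * np.sqrt(n / 2))  # rough slope-difference SE
        assert abs(d) < 3 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(InferenceError):
            slope_difference_curve(np.zeros((6, 2)), np.ones(6), np.arange(6) < 3)


class TestAUC:
    def test_constant_curve_rectangle(self):
        c = 2.5
        assert auc(np.full(30, c), DENSITIES) == pytest.approx(0.29 * c, rel=1e-12)

    def test_exact_for_linear_curves(self):
        curve = 3.0 * DENSITIES + 1.0
        exact = 3.0 * (0.30**2 - 0.01**2) / 2 + 1.0 * 0.29
        assert auc(curve, DENSITIES) == pytest.approx(exact, rel=1e-12)

    def test_matches_fine_riemann_oracle(self):
        rng = np.random.default_rng(6)
        curve = rng.standard_normal(30)
        assert auc(curve, DENSITIES) == pytest.approx(
            oracles.riemann_auc(curve, DENSITIES), rel=1e-6
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InferenceError):
            auc(np.zeros(5), DENSITIES)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(30)
        g = rng.standard_normal(30)
        assert auc(a * f + b * g, DENSITIES) == pytest.approx(
            a * auc(f, DENSITIES) + b * auc(g, DENSITIES), abs=1e-9
        )


class TestPermutationTest:
    def test_extreme_statistic_minimal_p(self):
        """If the observed statistic is the maximum achievable under any
        labeling, p = 1/(n_perm+1)."""
        n = 12
        values = np.zeros((n, 2))
        values[: n // 2] = 1.0  # risk group exactly the high-value half
        risk = np.arange(n) < n // 2
        res = permutation_test(values, risk, np.array([0.1, 0.2]), n_perm=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_two_tailed_relabel_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((20, 30))
        risk = np.arange(20) < 8
        r1 = permutation_test(values, risk, DENSITIES, n_perm=500, seed=3)
        r2 = permutation_test(values, ~risk, DENSITIES, n_perm=500, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.observed_auc == pytest.approx(-r2.observed_auc)

    def test_bit_reproducible_with_seed(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((15, 30))
        risk = np.arange(15) < 7
        r1 = permutation_test(values, risk, DENSITIES, n_perm=300, seed=11)
        r2 = permutation_test(values, risk, DENSITIES, n_perm=300, seed=11)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_aucs, r2.null_aucs)

    def test_null_p_values_stochastically_valid(self):
        """Under exchangeable data P(p <= alpha) <= alpha (within MC error)."""
        rng = np.random.default_rng(9)
        n_rep = 200
        hits = {0.05: 0, 0.1: 0, 0.2: 0}
        for rep in range(n_rep):
            values = rng.standard_normal((24, 10))
            risk = np.zeros(24, dtype=bool)
            risk[rng.choice(24, 10, replace=False)] = True
            res = permutation_test(
                values, risk, DENSITIES[:10], n_perm=99, seed=int(rng.integers(2**31))
            )
            for alpha in hits:
                hits[alpha] += res.p_value <= alpha
        for alpha, count in hits.items():
            rate = count / n_rep
            assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)

    def test_planted_shift_detected(self):
        """A 1.5-pooled-SD group shift at n=40/40 is detected (p < 0.05)
        in nearly all seeded replicates."""
        rng = np.random.default_rng(10)
        detected = 0
        n_rep = 60
        for rep in range(n_rep):
            base = rng.standard_normal((80, 10))
            risk = np.arange(80) < 40
            base[risk] += 1.5
            res = permutation_test(
                base, risk, DENSITIES[:10], n_perm=199, seed=int(rng.integers(2**31))
            )
            detected += res.p_value < 0.05
        assert detected / n_rep >= 0.95

    def test_slope_statistic_permutation(self):
        rng = np.random.default_rng(11)
        n = 60
        x = rng.normal(135.5, 18.9, n)
        risk = np.arange(n) < 25
        values = np.outer(np.where(risk, -0.05 * (x - 135.5) / 18.9, 0.0), np.ones(10))
        values += 0.05 * rng.standard_normal((n, 10))
        res = permutation_test(
            values, risk, DENSITIES[:10], statistic="slope_difference",
            neuroticism=x, n_perm=499, seed=1,
        )
        assert res.observed_auc < 0
        assert res.p_value < 0.05

    def test_invalid_nperm_rejected(self):
        with pytest.raises(InferenceError):
            permutation_test(np.zeros((6, 2)), np.arange(6) < 3, np.array([0.1, 0.2]), n_perm=0)
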