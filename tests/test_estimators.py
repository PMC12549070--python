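"""Estimators: hand-computed oracles, reductions, and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.stats.mstats import hdquantiles

from sampdist.estimators import (
    harrell_davis_quantile,
    harrell_davis_weights,
    pearson,
    pearson_critical_r,
    pearson_null_within,
    spearman,
    trimmed_mean,
    winsorized_variance,
    yuen_one_sample,
)

finite_floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


def _product_moment_r(x, y):
    """Oracle: the raw product-moment formula, written out term by term."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx = x - x.mean()
    sy = y - y.mean()
    return float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))


class TestPearson:
    def test_matches_hand_product_moment_formula(self):
        pairs = [(1, 2), (2, 1), (3, 4), (4, 3), (5, 6)]
        res = pearson(pairs)
        expected_r = _product_moment_r([p[0] for p in pairs], [p[1] for p in pairs])
        assert res.estimate == pytest.approx(expected_r, rel=1e-12)
        t = expected_r * math.sqrt(3 / (1 - expected_r**2))
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-12)

    def test_collinear_pairs_give_unit_correlation(self):
        pairs = [(x, 2 * x + 1) for x in range(5)]
        res = pearson(pairs)
        assert res.estimate == 1.0
        assert res.p_value == 0.0

    def test_negating_y_flips_sign_but_not_p(self):
        rng = np.random.default_rng(0)
        pairs = rng.normal(size=(20, 2))
        a = pearson(pairs)
        b = pearson(np.column_stack([pairs[:, 0], -pairs[:, 1]]))
        assert b.estimate == pytest.approx(-a.estimate, rel=1e-12)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([(1, 1), (1, 2), (1, 3)])  # zero variance in x
        with pytest.raises(ValueError):
            pearson([(1, 2), (2, 3)])  # too few pairs

    def test_null_p_values_uniform(self):
        """Under rho = 0 the two-sided p-values are uniform on [0, 1]."""
        rng = np.random.default_rng(123)
        n, reps = 20, 10_000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        ps = np.array([pearson(np.column_stack([xi, yi])).p_value for xi, yi in zip(x, y)])
        d = stats.ks_1samp(ps, stats.uniform.cdf).statistic
        assert d < 0.02


class TestSpearman:
    def test_strictly_monotone_gives_one(self):
        pairs = [(x, math.exp(x)) for x in range(1, 8)]
        assert spearman(pairs).estimate == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        pairs = [(x, -(x**3)) for x in range(1, 8)]
        assert spearman(pairs).estimate == pytest.approx(-1.0)

    def test_ties_use_mid_ranks(self):
        pairs = [(1, 1), (2, 1), (3, 2)]
        expected = _product_moment_r([1, 2, 3], [1.5, 1.5, 3])
        assert spearman(pairs).estimate == pytest.approx(expected, rel=1e-12)


class TestTrimmedMean:
    @pytest.mark.parametrize(
        "values, trim, expected",
        [
            (list(range(1, 11)), 0.2, 5.5),
            ([1, 2, 3, 4, 100], 0.2, 3.0),  # g=1: average of {2,3,4}
            ([7.0] * 6, 0.2, 7.0),
            ([1.0, 2.0, 3.0], 0.0, 2.0),
        ],
    )
    def test_examples(self, values, trim, expected):
        assert trimmed_mean(values, trim) == pytest.approx(expected)

    def test_invalid_trim_and_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0, 3.0], 0.5)
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0, 3.0], -0.1)
        with pytest.raises(ValueError):
            trimmed_mean([], 0.2)
        with pytest.raises(ValueError):
            winsorized_variance([1.0], 0.2)  # variance needs n >= 2

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(finite_floats, min_size=5, max_size=60), st.floats(0, 0.45))
    def test_permutation_invariant_and_bounded(self, values, trim):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(values)
        tm = trimmed_mean(values, trim)
        assert tm == pytest.approx(trimmed_mean(shuffled, trim), rel=1e-9, abs=1e-9)
        assert min(values) - 1e-9 <= tm <= max(values) + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(finite_floats, min_size=5, max_size=40),
        st.floats(0.1, 10.0),
        st.floats(-100.0, 100.0),
    )
    def test_affine_equivariance(self, values, a, b):
        lhs = trimmed_mean([a * v + b for v in values], 0.2)
        rhs = a * trimmed_mean(values, 0.2) + b
        assert lhs == pytest.approx(rhs, rel=1e-7, abs=1e-6)


class TestWinsorizedVariance:
    def test_constant_vector_is_zero(self):
        assert winsorized_variance([4.0] * 8, 0.2) == 0.0

    def test_zero_trim_is_ordinary_variance(self):
        assert winsorized_variance([1.0, 2.0, 3.0], 0.0) == pytest.approx(1.0)

    def test_hand_winsorization(self):
        # {1,2,3,4,100} with g=1 winsorizes to {2,2,3,4,4}: variance 1
        assert winsorized_variance([1, 2, 3, 4, 100], 0.2) == pytest.approx(1.0)


class TestYuenOneSample:
    def test_symmetric_data_about_null_gives_zero_statistic(self):
        res = yuen_one_sample([1.0, 2.0, 3.0, 4.0, 5.0], trim=0.2, null_value=3.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_trim_reduces_to_classic_t(self):
        """At trim=0 the statistic, df and p match the one-sample t to 12 digits."""
        rng = np.random.default_rng(21)
        data = rng.normal(0.4, 1.3, size=23)
        res = yuen_one_sample(data, trim=0.0, null_value=0.0)
        classic = stats.ttest_1samp(data, 0.0)
        assert res.statistic == pytest.approx(classic.statistic, rel=1e-12)
        assert res.df == classic.df
        assert res.p_value == pytest.approx(classic.pvalue, rel=1e-12)

    def test_type_one_error_calibrated_under_normal_null(self):
        """Rejection rate 0.05 ± 0.01 over 5,000 null simulations at n=30."""
        rng = np.random.default_rng(31)
        rejections = 0
        reps = 5_000
        for _ in range(reps):
            data = rng.normal(10.0, 2.0, size=30)
            if yuen_one_sample(data, trim=0.2, null_value=10.0).p_value <= 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_too_few_retained_rejected(self):
        with pytest.raises(ValueError):
            yuen_one_sample([1.0, 2.0, 3.0], trim=0.4)


class TestHarrellDavis:
    def test_single_value_returns_it(self):
        assert harrell_davis_quantile([42.0], 0.3) == 42.0

    def test_two_values_median_is_midpoint(self):
        assert harrell_davis_quantile([10.0, 20.0], 0.5) == pytest.approx(15.0)

    def test_quadrature_oracle_n5(self):
        """Weights from numerically integrating the Beta(3, 3) density."""
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        n, q = 5, 0.5
        a, b = (n + 1) * q, (n + 1) * (1 - q)
        weights = [
            integrate.quad(lambda u: stats.beta.pdf(u, a, b), (i - 1) / n, i / n)[0]
            for i in range(1, n + 1)
        ]
        expected = float(np.dot(sorted(values), weights))
        assert harrell_davis_quantile(values, q) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("q", [0.15, 0.5, 0.85])
    @pytest.mark.parametrize("n", [1, 2, 5, 17, 50, 200])
    def test_weights_sum_to_one(self, n, q):
        assert harrell_davis_weights(n, q).sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_independent_reference(self):
        """Cross-check against scipy's masked-stats Harrell–Davis implementation."""
        rng = np.random.default_rng(5)
        data = rng.gamma(2.0, 30.0, size=37) + 40
        for q in (0.15, 0.5, 0.85):
            ref = float(hdquantiles(data, prob=[q])[0])
            assert harrell_davis_quantile(data, q) == pytest.approx(ref, rel=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(finite_floats, min_size=1, max_size=40), st.floats(0.05, 0.95))
    def test_permutation_invariant_and_within_range(self, values, q):
        rng = np.random.default_rng(1)
        hd = harrell_davis_quantile(values, q)
        assert hd == pytest.approx(harrell_davis_quantile(rng.permutation(values), q), rel=1e-9, abs=1e-9)
        assert min(values) - 1e-6 <= hd <= max(values) + 1e-6

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(finite_floats, min_size=2, max_size=30), st.floats(0.1, 5.0), st.floats(-50.0, 50.0))
    def test_affine_equivariance(self, values, a, b):
        lhs = harrell_davis_quantile([a * v + b for v in values], 0.4)
        rhs = a * harrell_davis_quantile(values, 0.4) + b
        assert lhs == pytest.approx(rhs, rel=1e-7, abs=1e-6)


class TestPearsonNullWithin:
    def test_support_bound(self):
        assert pearson_null_within(1.0, 10) == pytest.approx(1.0)

    def test_strictly_increasing_in_n_and_margin(self):
        for n in (10, 30, 100):
            assert pearson_null_within(0.2, n + 1) > pearson_null_within(0.2, n)
            assert pearson_null_within(0.25, n) > pearson_null_within(0.2, n)

    def test_printed_thresholds(self):
        assert pearson_null_within(0.1, 110) >= 0.70
        assert pearson_null_within(0.2, 69) >= 0.90

    def test_monte_carlo_cross_check(self):
        """Analytic CDF of |r| under the null matches brute-force simulation."""
        rng = np.random.default_rng(77)
        n, reps, margin = 20, 200_000, 0.3
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        p_hat = np.mean(np.abs(r) <= margin)
        p = pearson_null_within(margin, n)
        se = math.sqrt(p * (1 - p) / reps)
        assert p_hat == pytest.approx(p, abs=3 * se)

    def test_out_of_range_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_null_within(0.0, 20)
        with pytest.raises(ValueError):
            pearson_null_within(1.5, 20)


class TestCriticalR:
    def test_matches_inverted_t(self):
        # at n=10, alpha=.05: t_crit on 8 df -> r_crit = t/sqrt(8 + t^2)
        t_crit = stats.t.isf(0.025, 8)
        assert pearson_critical_r(10, 0.05) == pytest.approx(t_crit / math.sqrt(8 + t_crit**2), rel=1e-12)

    def test_decreases_with_n(self):
        assert pearson_critical_r(100) < pearson_critical_r(10)
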