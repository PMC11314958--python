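"""Rank regression, signed-rank, FDR, partial Spearman, demographics tests."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from connectolesion.stats import (
    StatError,
    bh_fdr,
    cohen_d,
    fisher_exact,
    group_difference_test,
    mad_outlier_flags,
    mann_whitney,
    one_sample_signed_rank,
    partial_spearman,
    rank_fit,
)


class TestRankFit:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 1))
        fit = rank_fit(x, 2 * x[:, 0] + 3)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(3.0, abs=1e-8)
        assert fit.converged

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = X @ [1.5, -0.7] + rng.normal(size=40)
        f1 = rank_fit(X, y)
        X2 = X.copy()
        X2[:, 0] = 10 * X[:, 0] + 5  # location shift + scale
        f2 = rank_fit(X2, y)
        assert f2.coefficients[0] == pytest.approx(f1.coefficients[0] / 10, rel=1e-5)
        assert f2.coefficients[1] == pytest.approx(f1.coefficients[1], rel=1e-5)

    def test_more_robust_than_least_squares_under_contamination(self):
        rng = np.random.default_rng(2)
        wins = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=(40, 1))
            y = 2.0 * x[:, 0] + rng.normal(size=40)
            bad = rng.choice(40, size=4, replace=False)
            y[bad] += rng.choice([-1, 1], 4) * rng.uniform(15, 30, 4)
            b_rank = rank_fit(x, y).coefficients[0]
            b_ls = np.polyfit(x[:, 0], y, 1)[0]
            wins += abs(b_rank - 2) < abs(b_ls - 2)
        assert wins / reps >= 0.90

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(StatError, match="rank-deficient"):
            rank_fit(X, np.arange(10.0))

    def test_too_few_observations(self):
        with pytest.raises(StatError):
            rank_fit(np.ones((3, 2)), np.arange(3.0))


class TestGroupDifference:
    def test_cohen_d_hand_value(self):
        values = np.array([1, 2, 3, 3, 4, 5], float)
        assert cohen_d(values[:3], values[3:]) == pytest.approx(2.0)

    def test_exact_linear_structure(self):
        rng = np.random.default_rng(3)
        is_pd = np.repeat([False, True], [10, 12])
        cov = rng.normal(size=(22, 3))
        values = 5.0 * is_pd + cov @ [1.0, -2.0, 0.5]
        res = group_difference_test(values, is_pd, cov)
        assert res.group_coefficient == pytest.approx(5.0, abs=1e-6)

    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        coefs = []
        for _ in range(400):
            is_pd = np.repeat([False, True], [15, 19])
            cov = rng.normal(size=(34, 3))
            res = group_difference_test(rng.normal(size=34), is_pd, cov)
            coefs.append(res.group_coefficient)
        assert abs(np.mean(coefs)) < 0.1

    def test_small_group_rejected(self):
        with pytest.raises(StatError, match="too small"):
            group_difference_test(
                np.arange(8.0), np.repeat([False, True], [2, 6]), np.zeros((8, 0))
            )

    def test_zero_pooled_sd(self):
        with pytest.raises(StatError):
            cohen_d(np.ones(5), np.ones(6))


class TestSignedRank:
    def test_antisymmetric_values_give_p_one(self):
        assert one_sample_signed_rank([-3, -1, 1, 3, -2, 2]) == pytest.approx(1.0)

    def test_all_negative_extreme(self):
        p = one_sample_signed_rank([-1, -2, -3, -4, -5, -6])
        assert p == pytest.approx(2 / 2**6)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            v = rng.normal(0.3, 1, size=12)
            ours = one_sample_signed_rank(v)
            ref = sps.wilcoxon(v, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(6)
        rej = sum(
            one_sample_signed_rank(rng.normal(size=30)) < 0.05 for _ in range(500)
        )
        assert 0.03 <= rej / 500 <= 0.07

    def test_all_zero_rejected(self):
        with pytest.raises(StatError):
            one_sample_signed_rank(np.zeros(10))

    def test_too_few_rejected(self):
        with pytest.raises(StatError):
            one_sample_signed_rank([1.0, -2.0, 3.0, 4.0])


class TestBhFdr:
    def test_step_up_hand_example(self):
        assert bh_fdr([0.005, 0.05, 0.5]) == pytest.approx([0.015, 0.075, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_monotone_envelope(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_output_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(size=20))
        q = bh_fdr(p)
        assert (q >= p).all() and (np.diff(q) >= 0).all() and (q <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(StatError):
            bh_fdr([0.5, 1.2])


class TestPartialSpearman:
    def test_perfect_monotone(self):
        x = np.arange(20.0)
        r, p = partial_spearman(x, np.exp(x / 5))
        assert r == pytest.approx(1.0)

    def test_no_covariates_equals_classic_spearman(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, y = rng.normal(size=(2, 25))
            r, p = partial_spearman(x, y)
            ref_r, ref_p = sps.spearmanr(x, y)
            assert r == pytest.approx(ref_r, abs=1e-12)
            assert p == pytest.approx(ref_p, rel=1e-6)

    def test_null_rejection_rate_with_covariates(self):
        rng = np.random.default_rng(9)
        rej = 0
        reps = 500
        for _ in range(reps):
            z = rng.normal(size=(34, 3))
            x = z @ [0.5, 0.3, 0] + rng.normal(size=34)
            y = z @ [0.3, 0.5, 0.2] + rng.normal(size=34)
            rej += partial_spearman(x, y, z)[1] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_recovers_injected_partial_correlation(self):
        rng = np.random.default_rng(10)
        rho = -0.4
        ests = []
        for _ in range(300):
            z = rng.normal(size=(34, 2))
            u, v = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=34).T
            x = z @ [0.4, -0.3] + u
            y = z @ [0.3, 0.3] + v
            ests.append(partial_spearman(x, y, z)[0])
        # bivariate-normal Spearman of rho=-0.4 is (6/pi) asin(rho/2) = -0.385
        assert np.mean(ests) == pytest.approx(rho, abs=0.05)

    def test_constant_input_rejected(self):
        with pytest.raises(StatError, match="constant"):
            partial_spearman(np.ones(20), np.arange(20.0))


class TestDemographicsTests:
    def test_mann_whitney_exact_value(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_mann_whitney_null_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = [mann_whitney(rng.normal(size=30), rng.normal(size=30)) for _ in range(300)]
        assert 0.02 <= np.mean(np.array(ps) < 0.05) <= 0.09

    def test_mann_whitney_empty_rejected(self):
        with pytest.raises(StatError):
            mann_whitney([], [1.0])

    def test_fisher_hand_value(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_fisher_all_zero_rejected(self):
        with pytest.raises(StatError):
            fisher_exact([[0, 0], [0, 0]])


class TestOutlierFlags:
    def test_flags_gross_outlier_only(self):
        v = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.2, 0.8, 9.0])
        flags = mad_outlier_flags(v)
        assert flags[-1] and flags[:-1].sum() == 0

    def test_zero_mad_flags_nothing(self):
        assert not mad_outlier_flags(np.ones(10)).any()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40),
    st.integers(0, 2**31 - 1),
)
def test_all_p_values_in_unit_interval(values, seed):
    """Every p-value the machinery produces lies in [0, 1]."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values)
    n = v.size
    ps = []
    if np.ptp(v) > 0 and np.count_nonzero(v) >= 5:
        ps.append(one_sample_signed_rank(v))
    x = rng.normal(size=n)
    if np.ptp(v) > 0:
        ps.append(partial_spearman(x, v)[1])
        ps.append(mann_whitney(v[: n // 2], v[n // 2:]))
        X = rng.normal(size=(n, 2))
        fit = rank_fit(X, v)
        ps.extend(fit.p_values.tolist())
    ps.extend(bh_fdr(np.clip(np.abs(v[:5]) / 1e6, 0, 1)).tolist())
    assert all(0 <= p <= 1 for p in ps)
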