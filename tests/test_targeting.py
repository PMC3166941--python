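"""Unit and property tests for the targeting step."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tmlevim.targeting import (
    ConfoundingFit,
    DegenerateCovariateError,
    InitialFit,
    clever_covariate,
    fit_epsilon,
    influence_curve_variance,
    test_statistic as wald_statistic,
    tmle_from_arrays,
    update_beta,
    update_fitted,
)
from tmlevim.estimators import fit_univariate_initial


@pytest.mark.parametrize(
    "a, g, expected",
    [
        ([1, 2, 3], [0, 0, 0], [1, 2, 3]),
        ([1, 2, 3], [1, 2, 3], [0, 0, 0]),
        ([2, 4], [1, 1], [1, 3]),
    ],
)
def test_clever_covariate_is_elementwise_residual(a, g, expected):
    np.testing.assert_allclose(clever_covariate(a, ConfoundingFit(g)), expected)


def test_clever_covariate_rejects_length_mismatch():
    with pytest.raises(ValueError, match="length mismatch"):
        clever_covariate([1, 2], ConfoundingFit([1, 2, 3]))


@pytest.mark.parametrize(
    "r, c, expected",
    [
        ([0, 0, 0], [1, 2, 3], 0.0),
        ([1, 2, 3], [1, 0, 1], 2.0),
        ([1, -1], [1, 1], 0.0),
    ],
)
def test_fit_epsilon_hand_examples(r, c, expected):
    assert fit_epsilon(r, c) == pytest.approx(expected, abs=1e-12)


def test_fit_epsilon_degenerate_covariate():
    with pytest.raises(DegenerateCovariateError):
        fit_epsilon([1.0, 2.0], [0.0, 0.0])


@given(st.integers(0, 2**31 - 1))
def test_fit_epsilon_matches_lstsq_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 40))
    c = rng.standard_normal(n)
    r = rng.standard_normal(n)
    oracle = np.linalg.lstsq(c[:, None], r, rcond=None)[0][0]
    assert fit_epsilon(r, c) == pytest.approx(oracle, abs=1e-10)


def test_update_beta_and_fitted():
    init = InitialFit(beta0=1.2, q0=np.array([1.0, 1.0]))
    assert update_beta(init, -0.2) == pytest.approx(1.0)
    np.testing.assert_allclose(
        update_fitted(init, 0.5, [2.0, -2.0]), [2.0, 0.0]
    )
    np.testing.assert_allclose(update_fitted(init, 0.0, [5.0, 5.0]), init.q0)


def test_influence_curve_variance_hand_example():
    # c = (1,-1), residuals (1,1): mean c^2 = 1, IC = (1,-1), sigma2 = 2/4
    assert influence_curve_variance(
        [1.0, 1.0], [0.0, 0.0], [1.0, -1.0]
    ) == pytest.approx(0.5)


def test_influence_curve_variance_zero_for_perfect_fit(rng):
    y = rng.standard_normal(10)
    c = rng.standard_normal(10)
    assert influence_curve_variance(y, y, c) == pytest.approx(0.0)


def test_influence_curve_variance_residual_scaling(rng):
    y = rng.standard_normal(20)
    q = rng.standard_normal(20)
    c = rng.standard_normal(20)
    base = influence_curve_variance(y, q, c)
    doubled = influence_curve_variance(q + 2 * (y - q), q, c)
    assert doubled == pytest.approx(4 * base, rel=1e-12)


def test_wald_statistic_conventions_and_normal_tail():
    assert wald_statistic(0.0, 1.0) == (0.0, pytest.approx(1.0))
    t, p = wald_statistic(1.959964, 1.0)
    assert p == pytest.approx(0.05, abs=1e-6)
    t, p = wald_statistic(-2.575829, 1.0)
    assert p == pytest.approx(2 * stats.norm.cdf(-2.575829), rel=1e-9)
    assert p == pytest.approx(0.01, abs=1e-5)
    # sigma2 = 0 conventions
    assert wald_statistic(0.0, 0.0) == (0.0, 1.0)
    t, p = wald_statistic(1.0, 0.0)
    assert np.isinf(t) and p == 0.0


def test_tmle_toy_dataset_zero_fluctuation():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    a = np.array([0.0, 0.0, 1.0, 1.0])
    res = tmle_from_arrays(
        y, a,
        InitialFit(beta0=2.0, q0=np.array([1.5, 1.5, 3.5, 3.5])),
        ConfoundingFit(np.full(4, 0.5)),
    )
    assert res.epsilon == pytest.approx(0.0, abs=1e-12)
    assert res.beta_star == pytest.approx(2.0)
    assert res.t_stat == pytest.approx(res.beta_star / res.sigma)


@given(st.integers(0, 2**31 - 1))
def test_ols_initial_with_constant_g_forces_zero_epsilon(seed):
    """OLS residuals are orthogonal to the centered predictor, so the
    fluctuation vanishes exactly when g is the sample mean of A."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    a = rng.standard_normal(n)
    y = 0.7 * a + rng.standard_normal(n)
    init = fit_univariate_initial(y, a)
    res = tmle_from_arrays(y, a, init, ConfoundingFit(np.full(n, a.mean())))
    assert res.epsilon == pytest.approx(0.0, abs=1e-8)
    assert res.beta_star == pytest.approx(init.beta0, abs=1e-8)


@given(st.floats(0.1, 50.0), st.booleans(), st.integers(0, 2**31 - 1))
def test_outcome_scale_equivariance(k, negate, seed):
    """Replacing Y by kY scales beta* and sigma by |k|, leaving T and p
    unchanged (univariate initial estimator)."""
    if negate:
        k = -k
    rng = np.random.default_rng(seed)
    n = 40
    w = rng.standard_normal(n)
    a = 0.5 * w + rng.standard_normal(n)
    y = a + w + rng.standard_normal(n)
    g = ConfoundingFit(0.5 * w + 0.01)

    res1 = tmle_from_arrays(y, a, fit_univariate_initial(y, a), g)
    res2 = tmle_from_arrays(k * y, a, fit_univariate_initial(k * y, a), g)
    assert res2.beta_star == pytest.approx(k * res1.beta_star, rel=1e-9)
    assert res2.sigma == pytest.approx(abs(k) * res1.sigma, rel=1e-9)
    assert abs(res2.t_stat) == pytest.approx(abs(res1.t_stat), rel=1e-9)
    assert res2.p_value == pytest.approx(res1.p_value, rel=1e-6)


def test_null_t_statistic_is_bounded_over_replicates():
    """Under beta = 0 with independent A, W the statistic is approximately
    standard normal; |T| beyond 4 should essentially never occur."""
    rng = np.random.default_rng(2024)
    extreme = 0
    for _ in range(400):
        n = 200
        w = rng.standard_normal(n)
        a = rng.standard_normal(n)
        y = w + rng.standard_normal(n)
        res = tmle_from_arrays(y, a, fit_univariate_initial(y, a), ConfoundingFit(np.zeros(n)))
        extreme += abs(res.t_stat) > 4
    assert extreme == 0
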