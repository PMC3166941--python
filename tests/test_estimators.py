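"""Stage-1 estimators: univariate OLS, CV-lasso learner, grand fit + offset."""

import numpy as np
import pytest
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from tmlevim._gram_lasso import SharedLassoCVEngine
from tmlevim.estimators import (
    LassoLearner,
    fit_confounding,
    fit_lasso_learner,
    fit_univariate_initial,
    grand_initial,
    offset_initial_for,
)
from tmlevim.io import ExpressionDataset


@pytest.mark.parametrize(
    "y, a, beta0, q0",
    [
        ([1, 2, 3], [1, 2, 3], 1.0, [1, 2, 3]),
        ([1, 1, 1], [1, 2, 3], 0.0, [1, 1, 1]),
        ([0, 1, 1, 2], [0, 0, 1, 1], 1.0, [0.5, 0.5, 1.5, 1.5]),
    ],
)
def test_univariate_initial_hand_examples(y, a, beta0, q0):
    fit = fit_univariate_initial(y, a)
    assert fit.beta0 == pytest.approx(beta0, abs=1e-12)
    np.testing.assert_allclose(fit.q0, q0, atol=1e-12)


def test_univariate_initial_rejects_constant_predictor():
    with pytest.raises(ValueError, match="constant"):
        fit_univariate_initial([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


def test_lasso_learner_recovers_linear_support(rng):
    n, p = 300, 8
    x = rng.standard_normal((n, p))
    y = 2.0 * x[:, 3] + 0.3 * rng.standard_normal(n)
    learner = fit_lasso_learner(x, y, folds=5)
    coef = learner.coef_
    assert abs(coef[3]) > 1.0
    assert np.abs(np.delete(coef, 3)).max() < 0.2


def test_lasso_learner_full_shrinkage_limit(rng):
    # a one-alpha path at alpha_max shrinks every slope to zero
    n, p = 80, 5
    x = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    learner = LassoLearner(folds=4, n_alphas=1).train(x, y)
    assert np.abs(learner.coef_).max() == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(learner.predict(x), np.full(n, y.mean()), atol=1e-10)


def test_lasso_learner_duplicate_column_predictions_stable(rng):
    n = 200
    x = rng.standard_normal((n, 6))
    y = x[:, 0] - x[:, 2] + 0.5 * rng.standard_normal(n)
    dup = np.column_stack([x, x[:, 0]])
    p1 = fit_lasso_learner(x, y, folds=5).predict(x)
    p2 = fit_lasso_learner(dup, y, folds=5).predict(dup)
    assert np.mean((p1 - p2) ** 2) < 0.05 * np.var(y)


def test_lasso_learner_drops_zero_variance_columns(rng):
    x = rng.standard_normal((60, 4))
    x[:, 1] = 3.0
    y = x[:, 0] + 0.1 * rng.standard_normal(60)
    with pytest.warns(UserWarning, match="zero-variance"):
        learner = fit_lasso_learner(x, y, folds=4)
    assert learner.coef_[1] == 0.0


def test_lasso_learner_is_reproducible(rng):
    x = rng.standard_normal((100, 10))
    y = x[:, 0] + rng.standard_normal(100)
    c1 = fit_lasso_learner(x, y, folds=5).coef_
    c2 = fit_lasso_learner(x, y, folds=5).coef_
    np.testing.assert_array_equal(c1, c2)


def test_cv_lasso_never_much_worse_than_intercept_on_null(rng):
    """Held-out risk of the CV-lasso on pure-noise data stays within CV noise
    of the intercept-only model (penalty path sanity)."""
    n, p = 200, 30
    x = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    learner = fit_lasso_learner(x[:100], y[:100], folds=5)
    risk = np.mean((y[100:] - learner.predict(x[100:])) ** 2)
    base = np.mean((y[100:] - y[:100].mean()) ** 2)
    assert risk < base * 1.25


def _dataset(rng, n=120, p=6, beta=2.0):
    v = rng.standard_normal((n, p))
    y = beta * v[:, 0] + 0.5 * rng.standard_normal(n)
    return ExpressionDataset(y=y, v=v, ids=[f"g{j}" for j in range(p)])


def test_grand_fit_zero_substitution_linear_oracle(rng):
    ds = _dataset(rng, beta=2.0)
    grand = grand_initial(ds, LassoLearner(folds=5))
    shift = grand.predict_zeroed(0) - grand.fitted
    coef = grand.learner.coef_[0]
    np.testing.assert_allclose(shift, -coef * ds.v[:, 0], atol=1e-10)
    assert coef == pytest.approx(2.0, abs=0.3)
    # zero-coefficient column: substitution is a no-op
    null_col = int(np.argmin(np.abs(grand.learner.coef_)))
    if grand.learner.coef_[null_col] == 0.0:
        np.testing.assert_array_equal(grand.predict_zeroed(null_col), grand.fitted)


@pytest.mark.parametrize(
    "y, a, offset, expected",
    [
        ([2.0, 4.0], [1.0, 2.0], [1.0, 1.0], 1.4),  # (1*1 + 2*3) / (1+4)
        ([3.0, 6.0], [1.0, 2.0], [0.0, 0.0], 3.0),
    ],
)
def test_offset_regression_hand_examples(y, a, offset, expected):
    class _FixedOffset:
        def __init__(self, off, v):
            self.fitted = np.asarray(off)
            self.v = v

        def predict_zeroed(self, j):
            return self.fitted

    ds = ExpressionDataset(y=y, v=np.array(a)[:, None], ids=["g0"])
    fit = offset_initial_for(_FixedOffset(offset, ds.v), ds, 0)
    assert fit.beta0 == pytest.approx(expected, abs=1e-12)
    np.testing.assert_allclose(fit.q0, np.asarray(offset) + expected * np.asarray(a))


def test_offset_with_perfect_offset_gives_zero_slope(rng):
    ds = _dataset(rng)

    class _Oracle:
        fitted = ds.y

        def predict_zeroed(self, j):
            return ds.y

    fit = offset_initial_for(_Oracle(), ds, 0)
    assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.q0, ds.y)


def test_offset_and_univariate_betas_agree_when_grand_ignores_a(rng):
    """If the grand fit carries no A coefficient and predicts a constant,
    the offset slope matches the univariate OLS slope up to the intercept
    convention (no-intercept regression on mean-centered residuals)."""
    ds = _dataset(rng, n=400)
    a = ds.v[:, 0]

    class _MeanModel:
        fitted = np.full(ds.n, ds.y.mean())

        def predict_zeroed(self, j):
            return self.fitted

    offset_beta = offset_initial_for(_MeanModel(), ds, 0).beta0
    uni_beta = fit_univariate_initial(ds.y, a).beta0
    # differ only through the A-mean times intercept term, O(1/sqrt(n)) here
    assert offset_beta == pytest.approx(uni_beta, abs=0.15)


def test_fit_confounding_empty_w_gives_mean(rng):
    ds = _dataset(rng)
    g = fit_confounding(ds, 0, [], LassoLearner(folds=4))
    np.testing.assert_allclose(g.g, np.full(ds.n, ds.v[:, 0].mean()))


def test_fit_confounding_null_w_shrinks_to_mean(rng):
    n = 400
    v = rng.standard_normal((n, 10))
    ds = ExpressionDataset(y=rng.standard_normal(n), v=v, ids=[f"g{j}" for j in range(10)])
    g = fit_confounding(ds, 0, list(range(1, 10)), LassoLearner(folds=5))
    assert np.std(g.g) < 0.2  # fitted slopes shrink toward zero

    with pytest.raises(ValueError, match="exclude"):
        fit_confounding(ds, 0, [0, 1], LassoLearner(folds=5))


def test_shared_gram_engine_matches_lassocv(rng):
    """The per-dataset shared-Gram CV-lasso equals LassoCV with the same
    contiguous folds and alpha grid."""
    n, p = 150, 25
    f = rng.standard_normal((n, 1))
    v = 0.5 * f + rng.standard_normal((n, p))
    engine = SharedLassoCVEngine(v, folds=5, n_alphas=30, eps=1e-3, tol=1e-5)
    for j in (0, 7, 24):
        w = np.array([k for k in range(p) if k != j])
        g, n_used = engine.fit_g(j, w)
        ref = LassoCV(alphas=30, eps=1e-3, cv=KFold(5), tol=1e-5, max_iter=5000).fit(
            v[:, w], v[:, j]
        )
        assert n_used == p - 1
        np.testing.assert_allclose(g, ref.predict(v[:, w]), atol=1e-3)


def test_shared_gram_engine_screen_keeps_strong_candidates(rng):
    n = 300
    z = rng.standard_normal(n)
    v = np.column_stack([z + 0.3 * rng.standard_normal(n) for _ in range(3)]
                        + [rng.standard_normal(n) for _ in range(20)])
    engine = SharedLassoCVEngine(v, folds=5, screen=5)
    g, n_used = engine.fit_g(0, np.arange(1, 23))
    assert n_used == 5
    # the two strong correlates must survive the screen: g tracks column 0
    assert np.corrcoef(g, v[:, 0])[0, 1] > 0.7
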