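"""Stage-1 estimators: initial outcome fits and the confounding mechanism.

Two initial-estimator routes are provided. The *univariate* route fits the
ordinary least-squares line of Y on each target variable A, taking the slope
as ``beta0``. The *grand* route fits one penalized model of Y on all p
variables (``G(V)``), then, for each target A, regresses Y on A with the
offset ``G(A = 0)`` — the grand prediction with the A column zeroed — so the
expensive machine-learning fit is done once rather than p times.

The confounding mechanism ``g(W) ~ E(A | W)`` is fit per variable by any
:class:`RegressionLearner`; the default is an L1-penalized linear model with
the penalty chosen by k-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .targeting import ConfoundingFit, InitialFit

__all__ = [
    "RegressionLearner",
    "LassoLearner",
    "GrandFit",
    "fit_univariate_initial",
    "fit_lasso_learner",
    "grand_initial",
    "offset_initial_for",
    "fit_confounding",
]


@runtime_checkable
class RegressionLearner(Protocol):
    """Fitting contract for stage-1 learners."""

    name: str

    def train(self, x: np.ndarray, y: np.ndarray) -> "RegressionLearner": ...

    def predict(self, x: np.ndarray) -> np.ndarray: ...


def fit_univariate_initial(y, a_values) -> InitialFit:
    """OLS of Y on (intercept, A); beta0 is the slope, q0 the fitted line."""
    yv = np.asarray(y, dtype=float).ravel()
    a = np.asarray(a_values, dtype=float).ravel()
    if yv.shape != a.shape:
        raise ValueError("y and A must have the same length")
    n = yv.shape[0]
    if n < 3:
        raise ValueError("need at least three observations")
    a_c = a - a.mean()
    sxx = float(a_c @ a_c)
    if sxx <= 0.0:
        raise ValueError("degenerate predictor: A is constant")
    slope = float(a_c @ (yv - yv.mean())) / sxx
    intercept = yv.mean() - slope * a.mean()
    return InitialFit(beta0=slope, q0=intercept + slope * a)


class LassoLearner:
    """Cross-validated L1-penalized linear learner (squared-error loss).

    The penalty is chosen by k-fold cross-validation over a geometric path;
    folds are contiguous (no shuffling), so fits are reproducible without a
    random seed. Zero-variance columns are dropped with a warning before
    fitting and ignored at prediction time.
    """

    def __init__(
        self,
        folds: int = 10,
        n_alphas: int = 100,
        eps: float = 1e-3,
        max_iter: int = 5000,
        tol: float = 1e-4,
    ) -> None:
        self.folds = folds
        self.n_alphas = n_alphas
        self.eps = eps
        self.max_iter = max_iter
        self.tol = tol
        self.name = f"lasso-cv{folds}"
        self._model: LassoCV | None = None
        self._keep: np.ndarray | None = None

    def train(self, x: np.ndarray, y: np.ndarray) -> "LassoLearner":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y row counts differ")
        if x.shape[0] < self.folds:
            raise ValueError(f"need at least {self.folds} samples for CV")
        keep = x.std(axis=0) > 0.0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance column(s) before lasso"
            )
        if not keep.any():
            raise ValueError("all columns have zero variance")
        self._keep = keep
        self._model = LassoCV(
            eps=self.eps,
            alphas=self.n_alphas,
            cv=KFold(n_splits=self.folds, shuffle=False),
            max_iter=self.max_iter,
            tol=self.tol,
        ).fit(x[:, keep], y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("learner is not trained")
        x = np.asarray(x, dtype=float)
        return self._model.predict(x[:, self._keep])

    @property
    def coef_(self) -> np.ndarray:
        """Coefficients on the original column scale (zeros for dropped)."""
        if self._model is None:
            raise RuntimeError("learner is not trained")
        full = np.zeros(self._keep.shape[0])
        full[self._keep] = self._model.coef_
        return full

    @property
    def alpha_(self) -> float:
        if self._model is None:
            raise RuntimeError("learner is not trained")
        return float(self._model.alpha_)


def fit_lasso_learner(
    x, y, folds: int = 10, seed: int | None = None, **kwargs
) -> LassoLearner:
    """Convenience: train a :class:`LassoLearner` on (x, y).

    ``seed`` is accepted for interface symmetry; the learner is deterministic
    (contiguous CV folds, cyclic coordinate descent) so it is unused.
    """
    del seed
    return LassoLearner(folds=folds, **kwargs).train(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )


@dataclass
class GrandFit:
    """One fit of Y on all p variables, reusable for every target variable."""

    learner: RegressionLearner
    fitted: np.ndarray
    v: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.learner.predict(x)

    def predict_zeroed(self, a_index: int) -> np.ndarray:
        """Training-set predictions with column ``a_index`` set to zero,
        i.e. the offset ``G(A = 0)``."""
        if hasattr(self.learner, "coef_"):
            # Linear shortcut: zeroing a column shifts predictions by
            # -coef_j * V_j exactly.
            coef = self.learner.coef_[a_index]
            return self.fitted - coef * self.v[:, a_index]
        x0 = self.v.copy()
        x0[:, a_index] = 0.0
        return self.learner.predict(x0)


def grand_initial(dataset, learner: RegressionLearner) -> GrandFit:
    """Fit the grand estimate ``G(V) ~ E(Y | V)`` once."""
    trained = learner.train(dataset.v, dataset.y)
    return GrandFit(
        learner=trained, fitted=trained.predict(dataset.v), v=dataset.v
    )


def offset_initial_for(grand: GrandFit, dataset, a_index: int) -> InitialFit:
    """Per-variable initial fit from the grand estimate.

    Regresses ``Y - G(A=0)`` on A without intercept (the intercept and f(W)
    already live inside the offset); ``q0 = G(A=0) + beta0 * A``.
    """
    a = dataset.v[:, a_index]
    offset = grand.predict_zeroed(a_index)
    saa = float(a @ a)
    if saa <= 0.0:
        raise ValueError("degenerate predictor: A is identically zero")
    beta0 = float(a @ (dataset.y - offset)) / saa
    return InitialFit(beta0=beta0, q0=offset + beta0 * a)


def fit_confounding(
    dataset, a_index: int, w_indices, learner: RegressionLearner
) -> ConfoundingFit:
    """Fit ``g(W) ~ E(A | W)`` with the given learner.

    An empty confounder set carries no information, so g falls back to the
    sample mean of A (zero adjustment downstream).
    """
    w_indices = np.asarray(w_indices, dtype=int)
    if a_index in w_indices:
        raise ValueError("w_indices must exclude the target variable itself")
    a = dataset.v[:, a_index]
    if w_indices.size == 0:
        return ConfoundingFit(g=np.full(dataset.n, a.mean()))
    trained = learner.train(dataset.v[:, w_indices], a)
    return ConfoundingFit(g=trained.predict(dataset.v[:, w_indices]))
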