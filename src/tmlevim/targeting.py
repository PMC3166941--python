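"""The targeting (second-stage) step of the TMLE variable-importance estimator.

The semiparametric model is ``Y = beta * A + f(W)``: ``beta`` is the adjusted
marginal effect of the variable ``A`` on the outcome, with the arbitrary
confounder contribution ``f(W)`` absorbed into the stage-1 fitted values
``Q0 = Q(A, W)``. Given an initial estimate ``(beta0, Q0)`` and a fit
``g(W) ~ E(A | W)`` of the confounding mechanism, the targeting step

1. forms the clever covariate ``c_i = A_i - g(W_i)``,
2. regresses the stage-1 residuals ``Y - Q0`` on ``c`` without intercept,
   yielding the fluctuation coefficient ``epsilon``,
3. updates ``beta* = beta0 + epsilon`` and ``Q* = Q0 + epsilon * c``,
4. estimates the variance of ``beta*`` from the efficient influence curve
   ``IC_i = c_i (Y_i - Q*_i) / mean(c^2)``, and
5. tests ``beta = 0`` with ``T = beta* / sigma``, standard normal under the
   null as n grows.

``beta*`` is doubly robust: it is consistent when either the initial outcome
fit or ``g`` is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "InitialFit",
    "ConfoundingFit",
    "TMLEResult",
    "DegenerateCovariateError",
    "clever_covariate",
    "fit_epsilon",
    "update_beta",
    "update_fitted",
    "influence_curve_variance",
    "test_statistic",
    "tmle_single",
    "tmle_from_arrays",
]


class DegenerateCovariateError(ValueError):
    """The clever covariate is identically zero: A is fully explained by W,
    so the adjusted effect of A is not identifiable."""


@dataclass(frozen=True)
class InitialFit:
    """Stage-1 output: initial slope ``beta0`` and fitted values ``q0``."""

    beta0: float
    q0: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q0", np.asarray(self.q0, dtype=float).ravel())
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")
        if not np.isfinite(self.q0).all():
            raise ValueError("q0 must be finite")


@dataclass(frozen=True)
class ConfoundingFit:
    """Fitted confounding mechanism ``g_i ~ E(A_i | W_i)``."""

    g: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float).ravel())
        if not np.isfinite(self.g).all():
            raise ValueError("g must be finite")


@dataclass(frozen=True)
class TMLEResult:
    """One variable's targeted estimate with influence-curve inference."""

    epsilon: float
    beta_star: float
    sigma: float
    t_stat: float
    p_value: float
    n_confounders: int = 0
    delta_used: float | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def clever_covariate(a_values, g_fit: ConfoundingFit) -> np.ndarray:
    """Residual of the target variable on its confounders: ``A - g(W)``."""
    a = _as_1d(a_values, "a_values")
    if a.shape[0] != g_fit.g.shape[0]:
        raise ValueError(
            f"length mismatch: {a.shape[0]} A values vs {g_fit.g.shape[0]} g values"
        )
    return a - g_fit.g


def fit_epsilon(residuals, clever) -> float:
    """No-intercept least-squares slope of stage-1 residuals on the clever
    covariate. No intercept: f(W) is already absorbed in ``q0``."""
    r = _as_1d(residuals, "residuals")
    c = _as_1d(clever, "clever")
    if r.shape != c.shape:
        raise ValueError(f"length mismatch: {r.shape[0]} residuals vs {c.shape[0]}")
    denom = float(c @ c)
    if denom <= 0.0:
        raise DegenerateCovariateError(
            "clever covariate is identically zero (A fully explained by W)"
        )
    return float(r @ c) / denom


def update_beta(initial: InitialFit, epsilon: float) -> float:
    """Targeted update ``beta* = beta0 + epsilon``."""
    return float(initial.beta0 + epsilon)


def update_fitted(initial: InitialFit, epsilon: float, clever) -> np.ndarray:
    """Targeted fitted values ``Q* = Q0 + epsilon * c``."""
    c = _as_1d(clever, "clever")
    if c.shape != initial.q0.shape:
        raise ValueError("clever covariate and q0 lengths differ")
    return initial.q0 + epsilon * c


def influence_curve_variance(y, q_star, clever) -> float:
    """Efficient-influence-curve variance estimate of ``beta*``.

    ``IC_i = c_i (Y_i - Q*_i) / mean_j(c_j^2)``; the estimate is
    ``sigma^2 = sum(IC_i^2) / n^2``, i.e. the empirical variance of the IC
    divided by n.
    """
    yv = _as_1d(y, "y")
    q = _as_1d(q_star, "q_star")
    c = _as_1d(clever, "clever")
    if not (yv.shape == q.shape == c.shape):
        raise ValueError("y, q_star and clever must have equal lengths")
    n = yv.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    mean_c2 = float(c @ c) / n
    if mean_c2 <= 0.0:
        raise DegenerateCovariateError("clever covariate is identically zero")
    ic = c * (yv - q) / mean_c2
    return float(ic @ ic) / n**2


def test_statistic(beta_star: float, sigma2: float) -> tuple[float, float]:
    """Wald statistic ``T = beta*/sigma`` and its two-sided normal p-value.

    ``sigma2 == 0`` conventions: T = 0, p = 1 when ``beta*`` is 0 (a perfectly
    fitted, exactly null toy input); an infinite statistic with p = 0
    otherwise. Two-sided because the sign of an importance is not
    prespecified.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 == 0.0:
        if beta_star == 0.0:
            return 0.0, 1.0
        return float(np.sign(beta_star) * np.inf), 0.0
    t = beta_star / np.sqrt(sigma2)
    p = 2.0 * float(stats.norm.sf(abs(t)))
    return float(t), min(p, 1.0)


def tmle_from_arrays(
    y,
    a_values,
    initial: InitialFit,
    g_fit: ConfoundingFit,
    n_confounders: int = 0,
    delta_used: float | None = None,
) -> TMLEResult:
    """Run the full targeting chain on raw arrays."""
    yv = _as_1d(y, "y")
    a = _as_1d(a_values, "a_values")
    if not (yv.shape == a.shape == initial.q0.shape == g_fit.g.shape):
        raise ValueError("y, A, q0 and g must all have the same length")
    c = clever_covariate(a, g_fit)
    eps = fit_epsilon(yv - initial.q0, c)
    beta_star = update_beta(initial, eps)
    q_star = update_fitted(initial, eps, c)
    sigma2 = influence_curve_variance(yv, q_star, c)
    t, p = test_statistic(beta_star, sigma2)
    flags: tuple[str, ...] = ()
    if sigma2 == 0.0 and beta_star != 0.0:
        flags = ("infinite_statistic",)
    return TMLEResult(
        epsilon=eps,
        beta_star=beta_star,
        sigma=float(np.sqrt(sigma2)),
        t_stat=t,
        p_value=p,
        n_confounders=n_confounders,
        delta_used=delta_used,
        flags=flags,
    )


def tmle_single(
    dataset,
    a_index: int,
    initial: InitialFit,
    g_fit: ConfoundingFit,
    n_confounders: int = 0,
    delta_used: float | None = None,
) -> TMLEResult:
    """Targeted VIM estimate for column ``a_index`` of a dataset."""
    return tmle_from_arrays(
        dataset.y,
        dataset.v[:, a_index],
        initial,
        g_fit,
        n_confounders=n_confounders,
        delta_used=delta_used,
    )
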