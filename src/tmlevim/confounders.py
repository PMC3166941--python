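"""Confounder selection for each target variable.

Which columns enter ``W`` when fitting the confounding mechanism of a target
``A``? Columns nearly collinear with ``A`` make the adjusted effect
unidentifiable (the clever covariate degenerates), so candidates are limited
to columns whose absolute Pearson correlation with ``A`` is *below* a cutoff
``delta``. A universal cutoff of 0.7 is a conservative standard choice; the
adaptive variant tries a grid of cutoffs per variable and keeps the largest
one whose targeted p-value stays below a threshold ``lambda`` — the smaller
the ``lambda``, the more protection against over-adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimators import fit_confounding
from .targeting import DegenerateCovariateError, TMLEResult, tmle_single

__all__ = ["AdaptiveConfig", "select_confounders", "adaptive_delta"]

DEFAULT_DELTA = 0.7


@dataclass(frozen=True)
class AdaptiveConfig:
    """Grid of correlation cutoffs and the qualifying p-value threshold."""

    delta_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
    lam: float = 0.05

    def __post_init__(self) -> None:
        grid = tuple(float(d) for d in self.delta_grid)
        object.__setattr__(self, "delta_grid", grid)
        if not grid:
            raise ValueError("delta grid must be nonempty")
        if any(not 0.0 < d <= 1.0 for d in grid):
            raise ValueError("every delta must lie in (0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("delta grid must be strictly increasing")
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lambda must lie in (0, 1)")


def _corr_with_column(v: np.ndarray, a_index: int) -> np.ndarray:
    vc = v - v.mean(axis=0)
    sd = vc.std(axis=0)
    a = vc[:, a_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (vc.T @ a) / (v.shape[0] * np.outer(sd, [sd[a_index]]).ravel())
    corr[~np.isfinite(corr)] = np.nan
    return corr


def select_confounders(
    v: np.ndarray, a_index: int, delta: float, corr: np.ndarray | None = None
) -> np.ndarray:
    """Indices j != a_index with ``|cor(V_j, A)| < delta`` (strict).

    ``corr`` may supply a precomputed full correlation matrix (zero-variance
    columns encoded as zero correlation are still excluded here, with a
    warning, based on the column variances of ``v``).
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0, 1]")
    v = np.asarray(v, dtype=float)
    if corr is not None:
        r = np.asarray(corr[a_index], dtype=float).copy()
    else:
        r = _corr_with_column(v, a_index)
    zero_var = v.std(axis=0) == 0.0
    if zero_var.any():
        warnings.warn(
            f"excluding {int(zero_var.sum())} zero-variance column(s) from "
            "confounder selection"
        )
    r[zero_var] = np.nan
    mask = np.abs(r) < delta
    mask[a_index] = False
    mask &= ~np.isnan(r)
    return np.flatnonzero(mask)


def adaptive_delta(
    dataset,
    a_index: int,
    config: AdaptiveConfig,
    initial,
    learner=None,
    corr: np.ndarray | None = None,
    g_factory=None,
) -> tuple[float, TMLEResult]:
    """Adaptive per-variable correlation cutoff.

    Computes a targeted estimate at every cutoff in the grid and returns the
    largest ``delta`` whose p-value is below ``lambda`` with its result. If no
    cutoff qualifies, the smallest-cutoff result is returned flagged
    ``no_delta_qualified`` so the variable keeps a p-value. Cutoffs whose
    clever covariate degenerates are skipped with a warning.

    ``g_factory(j, w_indices) -> ConfoundingFit`` may replace the generic
    per-cutoff ``fit_confounding(learner)`` route (the pipeline passes the
    shared-Gram engine through it).
    """
    if learner is None and g_factory is None:
        raise ValueError("provide a learner or a g_factory")
    if g_factory is None:
        def g_factory(j, w_idx):  # noqa: ANN001 - generic route
            return fit_confounding(dataset, j, w_idx, learner), len(w_idx)

    results: list[tuple[float, TMLEResult]] = []
    cache: dict[tuple[int, ...], TMLEResult] = {}
    for delta in config.delta_grid:
        w_idx = select_confounders(dataset.v, a_index, delta, corr=corr)
        key = tuple(w_idx)
        if key in cache:
            prev = cache[key]
            res = TMLEResult(
                epsilon=prev.epsilon,
                beta_star=prev.beta_star,
                sigma=prev.sigma,
                t_stat=prev.t_stat,
                p_value=prev.p_value,
                n_confounders=prev.n_confounders,
                delta_used=delta,
                flags=prev.flags,
            )
        else:
            try:
                g_fit, n_used = g_factory(a_index, w_idx)
                res = tmle_single(
                    dataset,
                    a_index,
                    initial,
                    g_fit,
                    n_confounders=n_used,
                    delta_used=delta,
                )
            except DegenerateCovariateError:
                warnings.warn(
                    f"delta={delta:g}: clever covariate degenerate, skipping"
                )
                continue
            cache[key] = res
        results.append((delta, res))

    if not results:
        raise DegenerateCovariateError(
            "every cutoff in the grid produced a degenerate clever covariate"
        )
    qualifying = [(d, r) for d, r in results if r.p_value < config.lam]
    if qualifying:
        return qualifying[-1]
    delta, res = results[0]
    flagged = TMLEResult(
        epsilon=res.epsilon,
        beta_star=res.beta_star,
        sigma=res.sigma,
        t_stat=res.t_stat,
        p_value=res.p_value,
        n_confounders=res.n_confounders,
        delta_used=delta,
        flags=res.flags + ("no_delta_qualified",),
    )
    return delta, flagged
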