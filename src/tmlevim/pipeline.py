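"""Orchestration: per-variable targeted VIM across a dataset, the univariate
baseline, FDR adjustment, ranking and list truncation.

``compute_all_vim`` walks every column of the variable matrix, builds its
initial fit (univariate OLS or grand-lasso-with-offset), fits its confounding
mechanism on the selected confounders, runs the targeting step and assembles a
table of per-variable estimates with Benjamini-Hochberg adjusted p-values and
ranks. ``ur_vim`` is the classical per-gene simple-regression baseline used
throughout as the comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._gram_lasso import SharedLassoCVEngine
from .confounders import DEFAULT_DELTA, AdaptiveConfig, adaptive_delta, select_confounders
from .estimators import LassoLearner, fit_univariate_initial, grand_initial, offset_initial_for
from .targeting import ConfoundingFit, DegenerateCovariateError, InitialFit, tmle_single

__all__ = ["RunConfig", "compute_all_vim", "ur_vim", "adjust_fdr", "reduce_list"]

TRUNCATION_RULES = ("p", "fdr", "top_k")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    initial: "univariate" or "grand-lasso" stage-1 estimator.
    delta: universal correlation cutoff for confounder selection, ignored
        when ``adaptive`` is set.
    adaptive: optional :class:`AdaptiveConfig` enabling the per-variable
        adaptive cutoff.
    rule/threshold/top_k: exactly one truncation rule — raw p-value threshold
        ("p"), FDR-adjusted threshold ("fdr") or top-k by rank ("top_k").
    folds / n_alphas / eps: cross-validation folds and penalty path of the
        lasso fits (both the grand initial fit and the confounding fits).
    g_screen: optional cap on the number of confounder candidates offered to
        each lasso g-fit (strongest |correlation| with A first); None fits on
        all selected confounders.
    seed: recorded for provenance; all fits here are deterministic.
    """

    initial: str = "grand-lasso"
    delta: float = DEFAULT_DELTA
    adaptive: AdaptiveConfig | None = None
    rule: str = "p"
    threshold: float = 0.05
    top_k: int | None = None
    folds: int = 10
    n_alphas: int = 50
    eps: float = 1e-2
    g_screen: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial not in ("univariate", "grand-lasso"):
            raise ValueError(f"unknown initial estimator {self.initial!r}")
        if self.rule not in TRUNCATION_RULES:
            raise ValueError(f"truncation rule must be one of {TRUNCATION_RULES}")
        if self.rule == "top_k" and self.top_k is None:
            raise ValueError("top_k rule needs a k")
        if self.rule != "top_k" and self.top_k is not None:
            raise ValueError("top_k set but the truncation rule is not 'top_k'")
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must lie in (0, 1]")

    def truncation(self) -> tuple:
        if self.rule == "top_k":
            return ("top_k", self.top_k)
        return (self.rule, self.threshold)

    def as_dict(self) -> dict:
        d = {
            "initial": self.initial,
            "delta": self.delta,
            "rule": self.rule,
            "threshold": self.threshold,
            "top_k": self.top_k,
            "folds": self.folds,
            "n_alphas": self.n_alphas,
            "eps": self.eps,
            "g_screen": self.g_screen,
            "seed": self.seed,
        }
        if self.adaptive is not None:
            d["adaptive_grid"] = list(self.adaptive.delta_grid)
            d["adaptive_lambda"] = self.adaptive.lam
        return d


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_and_select(df: pd.DataFrame, truncation: tuple) -> pd.DataFrame:
    order = np.argsort(df["p"].to_numpy(), kind="stable")  # ties: column order
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    kind, value = truncation
    if kind == "p":
        selected = df["p"].to_numpy() < value
    elif kind == "fdr":
        selected = df["p_adj"].to_numpy() < value
    elif kind == "top_k":
        if value > len(df):
            warnings.warn(f"top_k={value} exceeds {len(df)} variables; keeping all")
        selected = rank <= value
    else:
        raise ValueError(f"unknown truncation rule {kind!r}")
    df["selected"] = selected
    return df


def compute_all_vim(dataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Targeted VIM table for every variable in the dataset.

    Degenerate variables (constant columns, or columns whose clever covariate
    vanishes) are kept in the table with p = 1 and a flag rather than dropped,
    so the table shape is stable. Deterministic given the dataset.
    """
    config = config or RunConfig()
    n, p = dataset.n, dataset.p
    engine = SharedLassoCVEngine(
        dataset.v,
        folds=config.folds,
        n_alphas=config.n_alphas,
        eps=config.eps,
        screen=config.g_screen,
    )
    corr = engine.corr
    col_sd = dataset.v.std(axis=0)

    grand = None
    if config.initial == "grand-lasso":
        learner = LassoLearner(
            folds=config.folds, n_alphas=config.n_alphas, eps=config.eps
        )
        try:
            grand = grand_initial(dataset, learner)
        except Exception as exc:  # noqa: BLE001 - diagnostic rewrap
            raise RuntimeError(f"grand initial fit failed: {exc}") from exc

    def g_factory(j: int, w_idx) -> tuple[ConfoundingFit, int]:
        g, n_used = engine.fit_g(j, w_idx)
        return ConfoundingFit(g=g), n_used

    rows = []
    for j in range(p):
        flags: list[str] = []
        if col_sd[j] == 0.0:
            rows.append(
                dict(
                    id=dataset.ids[j], beta=0.0, se=0.0, t=0.0, p=1.0,
                    n_confounders=0, delta_used=np.nan,
                    flags="constant_variable",
                )
            )
            continue
        try:
            if config.initial == "univariate":
                initial = fit_univariate_initial(dataset.y, dataset.v[:, j])
            else:
                initial = offset_initial_for(grand, dataset, j)
            if config.adaptive is not None:
                _, res = adaptive_delta(
                    dataset, j, config.adaptive, initial,
                    corr=corr, g_factory=g_factory,
                )
            else:
                w_idx = select_confounders(dataset.v, j, config.delta, corr=corr)
                g_fit, n_used = g_factory(j, w_idx)
                res = tmle_single(
                    dataset, j, initial, g_fit,
                    n_confounders=n_used, delta_used=config.delta,
                )
        except DegenerateCovariateError:
            rows.append(
                dict(
                    id=dataset.ids[j], beta=0.0, se=0.0, t=0.0, p=1.0,
                    n_confounders=0, delta_used=np.nan,
                    flags="degenerate_covariate",
                )
            )
            continue
        except Exception as exc:  # noqa: BLE001 - diagnostic naming the variable
            raise RuntimeError(
                f"VIM computation failed for variable {dataset.ids[j]!r}: {exc}"
            ) from exc
        flags.extend(res.flags)
        rows.append(
            dict(
                id=dataset.ids[j],
                beta=res.beta_star,
                se=res.sigma,
                t=res.t_stat,
                p=res.p_value,
                n_confounders=res.n_confounders,
                delta_used=res.delta_used if res.delta_used is not None else np.nan,
                flags=";".join(flags),
            )
        )

    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_fdr(df["p"].to_numpy())
    return _rank_and_select(df, config.truncation())[
        ["id", "beta", "se", "t", "p", "p_adj", "rank", "selected",
         "n_confounders", "delta_used", "flags"]
    ]


def ur_vim(dataset, truncation: tuple = ("p", 0.05)) -> pd.DataFrame:
    """Univariate-regression baseline: per-variable OLS of Y on (1, A) with
    the textbook two-sided t-test on the slope. Same table schema as
    :func:`compute_all_vim`."""
    y = dataset.y
    n = dataset.n
    if n < 3:
        raise ValueError("need at least three samples")
    if np.unique(y).size == 1:
        warnings.warn("outcome is constant; all p-values are 1")
    vc = dataset.v - dataset.v.mean(axis=0)
    yc = y - y.mean()
    sxx = (vc**2).sum(axis=0)
    sxy = vc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > 0.0
    beta = np.zeros(dataset.p)
    beta[ok] = sxy[ok] / sxx[ok]
    sse = np.maximum(syy - beta * sxy, 0.0)
    se = np.zeros(dataset.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sse[ok] / (n - 2) / sxx[ok])
    t = np.zeros(dataset.p)
    nonzero = ok & (se > 0)
    t[nonzero] = beta[nonzero] / se[nonzero]
    pvals = np.ones(dataset.p)
    pvals[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), df=n - 2)
    # exact fit (se == 0) with a nonzero slope: overwhelming evidence
    exact = ok & (se == 0.0) & (beta != 0.0)
    pvals[exact] = 0.0
    t[exact] = np.sign(beta[exact]) * np.inf

    flags = np.where(ok, "", "constant_variable")
    df = pd.DataFrame(
        dict(
            id=dataset.ids, beta=beta, se=se, t=t, p=np.clip(pvals, 0, 1),
            n_confounders=0, delta_used=np.nan, flags=flags,
        )
    )
    df["p_adj"] = adjust_fdr(df["p"].to_numpy())
    return _rank_and_select(df, truncation)[
        ["id", "beta", "se", "t", "p", "p_adj", "rank", "selected",
         "n_confounders", "delta_used", "flags"]
    ]


def reduce_list(table: pd.DataFrame, rule: tuple) -> list[str]:
    """Truncate a VIM table to a candidate identifier list, in rank order.

    ``rule`` is ("p", threshold), ("fdr", threshold) or ("top_k", k).
    """
    kind, value = rule
    ordered = table.sort_values("rank", kind="stable")
    if kind == "p":
        keep = ordered[ordered["p"] < value]
    elif kind == "fdr":
        keep = ordered[ordered["p_adj"] < value]
    elif kind == "top_k":
        if value > len(ordered):
            warnings.warn(f"top_k={value} exceeds {len(ordered)} variables")
        keep = ordered.head(max(int(value), 0))
    else:
        raise ValueError(f"unknown truncation rule {kind!r}")
    return keep["id"].tolist()
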