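"""Downstream prediction on reduced variable lists and benchmark summaries.

The screening methods are compared by what they enable downstream: fit a
predictor on each method's reduced list, measure its L2 risk on held-out
data, and summarize

* ``R_r`` — proportional risk reduction, (UR risk - TMLE risk) / UR risk;
* ``R_A`` — ratio of truly causal variables recovered, TMLE / UR;
* ``R_W`` — ratio of false positives, TMLE / UR;
* ``R^2`` — 1 - risk / MST, MST the mean squared deviation of the test
  outcome from its mean.

Two downstream predictors are provided: multivariate linear regression (MVR),
which has no internal model selection and therefore exposes the quality of
the list directly, and a cross-validated L1 fit.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .estimators import LassoLearner
from .pipeline import RunConfig, compute_all_vim, reduce_list, ur_vim
from .simulate import ClusterDesign, simulate_cluster

__all__ = [
    "DownstreamPredictor",
    "l2_risk",
    "r_squared",
    "fit_downstream",
    "run_cluster_replicate",
    "benchmark",
    "write_report",
]


class DownstreamPredictor:
    """Predictor over a named subset of variables of a dataset."""

    def __init__(self, ids: list[str], kind: str, intercept: float,
                 coef: np.ndarray | None = None, model: LassoLearner | None = None):
        self.ids = list(ids)
        self.kind = kind
        self.intercept = intercept
        self.coef = coef
        self.model = model

    def predict(self, dataset) -> np.ndarray:
        cols = [dataset.column(i) for i in self.ids]
        x = dataset.v[:, cols]
        if self.kind == "mvr":
            return self.intercept + x @ self.coef
        return self.model.predict(x)


def l2_risk(predictor, test_dataset) -> float:
    """Mean squared prediction error on a test dataset.

    ``predictor`` is anything with a ``predict(dataset)`` method, or a
    callable taking the dataset.
    """
    yhat = (
        predictor.predict(test_dataset)
        if hasattr(predictor, "predict")
        else predictor(test_dataset)
    )
    yhat = np.asarray(yhat, dtype=float).ravel()
    if yhat.shape[0] != test_dataset.n:
        raise ValueError("prediction length does not match the test set")
    return float(np.mean((test_dataset.y - yhat) ** 2))


def r_squared(risk: float, y_test) -> float:
    """Proportion of test-outcome variance explained: 1 - risk / MST."""
    y = np.asarray(y_test, dtype=float).ravel()
    mst = float(np.mean((y - y.mean()) ** 2))
    if mst <= 0.0:
        raise ValueError("test outcome has zero variance")
    return 1.0 - risk / mst


def fit_downstream(
    dataset, selected_ids, method: str = "mvr", folds: int = 5
) -> DownstreamPredictor:
    """Fit the downstream predictor on the selected columns.

    MVR refuses designs with as many variables as samples (it is exactly the
    breakdown regime the benchmarks are probing); use the L1 predictor there.
    """
    ids = list(selected_ids)
    if not ids:
        raise ValueError("selection is empty; nothing to fit")
    cols = [dataset.column(i) for i in ids]
    x = dataset.v[:, cols]
    if method == "mvr":
        if len(ids) >= dataset.n:
            raise ValueError(
                f"MVR with {len(ids)} variables and {dataset.n} samples is rank "
                "deficient; use the 'lasso' downstream predictor"
            )
        design = np.column_stack([np.ones(dataset.n), x])
        coef, *_ = np.linalg.lstsq(design, dataset.y, rcond=None)
        return DownstreamPredictor(ids, "mvr", float(coef[0]), coef=coef[1:])
    if method == "lasso":
        model = LassoLearner(folds=folds).train(x, dataset.y)
        return DownstreamPredictor(ids, "lasso", 0.0, model=model)
    raise ValueError(f"unknown downstream method {method!r}")


class _MeanPredictor:
    def __init__(self, mean: float) -> None:
        self.mean = mean

    def predict(self, dataset) -> np.ndarray:
        return np.full(dataset.n, self.mean)


def _counts(ids: list[str], dataset) -> tuple[int, int]:
    if dataset.truth is None:
        raise ValueError("dataset has no truth flags")
    truth_ids = {dataset.ids[j] for j in np.flatnonzero(dataset.truth)}
    tp = sum(1 for i in ids if i in truth_ids)
    return tp, len(ids) - tp


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def run_cluster_replicate(
    design: ClusterDesign,
    seed: int,
    vim_config: RunConfig | None = None,
    truncation: tuple = ("p", 0.05),
    n_test: int = 5000,
    include_shifted_test: bool = False,
    downstream: str = "mvr",
) -> dict:
    """One train/test replicate of the cluster benchmark.

    Trains both screens (UR and targeted) on a fresh training draw, truncates
    both lists with the same rule, fits the downstream predictor on each list
    and evaluates on testing set (a) (same rho) and, optionally, testing set
    (b) (rho = 0.1, same coefficients). An empty list falls back to the
    training-mean predictor (flagged in the output).
    """
    vim_config = vim_config or RunConfig()
    train = simulate_cluster(dataclasses.replace(design, seed=seed))
    test_a = simulate_cluster(
        dataclasses.replace(design, n=n_test, seed=seed + 1_000_003)
    )
    test_b = None
    if include_shifted_test:
        test_b = simulate_cluster(
            dataclasses.replace(design, n=n_test, rho=0.1, seed=seed + 2_000_003)
        )

    tables = {
        "ur": ur_vim(train, truncation=truncation),
        "tmle": compute_all_vim(train, vim_config),
    }
    out: dict = {"seed": seed, "rho": design.rho, "m_w": design.m_w}
    risks: dict[str, dict[str, float]] = {}
    for name, table in tables.items():
        ids = reduce_list(table, truncation)
        tp, fp = _counts(ids, train)
        out[f"{name}_n_selected"] = len(ids)
        out[f"{name}_tp"] = tp
        out[f"{name}_fp"] = fp
        if ids:
            predictor = fit_downstream(train, ids, method=downstream)
        else:
            warnings.warn(f"{name}: empty selection, falling back to mean predictor")
            predictor = _MeanPredictor(float(train.y.mean()))
            out[f"{name}_empty_selection"] = True
        risks[name] = {"a": l2_risk(predictor, test_a)}
        if test_b is not None:
            risks[name]["b"] = l2_risk(predictor, test_b)
        out[f"{name}_risk_a"] = risks[name]["a"]
        if test_b is not None:
            out[f"{name}_risk_b"] = risks[name]["b"]

    out["r_r_a"] = _safe_ratio(
        risks["ur"]["a"] - risks["tmle"]["a"], risks["ur"]["a"]
    )
    if test_b is not None:
        out["r_r_b"] = _safe_ratio(
            risks["ur"]["b"] - risks["tmle"]["b"], risks["ur"]["b"]
        )
    out["r_a"] = _safe_ratio(out["tmle_tp"], out["ur_tp"])
    out["r_w"] = _safe_ratio(out["tmle_fp"], out["ur_fp"])
    return out


def benchmark(
    designs,
    replicates: int = 3,
    seed: int = 0,
    vim_config: RunConfig | None = None,
    truncation: tuple = ("p", 0.05),
    n_test: int = 5000,
    include_shifted_test: bool = False,
    downstream: str = "mvr",
) -> pd.DataFrame:
    """Replicated cluster benchmark over a grid of designs.

    Returns one row per design with replicate means and standard errors of
    the risks, ratios and counts. Fully reproducible from (designs, seed,
    replicates). Undefined ratios (zero denominators) propagate as NaN while
    the raw counts remain reported.
    """
    rows = []
    for d_i, design in enumerate(designs):
        reps = [
            run_cluster_replicate(
                design,
                seed=seed + 10_000 * d_i + 17 * r,
                vim_config=vim_config,
                truncation=truncation,
                n_test=n_test,
                include_shifted_test=include_shifted_test,
                downstream=downstream,
            )
            for r in range(replicates)
        ]
        df = pd.DataFrame(reps)
        row = {
            "rho": design.rho,
            "m_w": design.m_w,
            "sigma_e": design.sigma_e,
            "n": design.n,
            "replicates": replicates,
            "downstream": downstream,
        }
        for col in df.columns:
            if col in ("seed", "rho", "m_w"):
                continue
            vals = df[col].astype(float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path, seed: int | None = None,
                 config: dict | None = None) -> None:
    """Write a benchmark report as TSV with a provenance header."""
    from .io import _provenance_header

    with open(path, "w") as fh:
        fh.write(_provenance_header(seed, config))
        report.to_csv(fh, sep="\t", index=False, float_format="%.17g")
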