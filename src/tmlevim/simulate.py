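"""Seeded synthetic-data generators for the two study designs.

*Cluster design* — 25 independent clusters of covariates. Each cluster holds
one causal variable A and its m correlated companions W, jointly multivariate
normal with mean zero, unit variances and a single exchangeable within-cluster
correlation ``rho``; clusters are mutually independent. The outcome is a main
effect model of the 25 A's plus Gaussian noise of scale ``sigma_e``. The
design stores its coefficients, so a test set drawn at a different ``rho``
(``dataclasses.replace(design, rho=..., seed=...)``) keeps the causal
mechanism fixed while the covariate joint distribution changes.

*General design* — rows drawn multivariate normal under an arbitrary supplied
correlation matrix (e.g. one mimicking an expression study), with the outcome
built from a designated set of causal columns by a linear or polynomial form.

*Null design* — covariates as in the cluster scheme, outcome pure independent
noise; used for type-I-error calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = [
    "ClusterDesign",
    "GeneralDesign",
    "simulate_cluster",
    "simulate_general",
    "simulate_null",
    "synthetic_expression_corr",
]


def _exchangeable_block(rng: np.random.Generator, n: int, size: int, rho: float) -> np.ndarray:
    """n x size draws, unit variance, all pairwise correlations rho."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, size))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


@dataclass(frozen=True)
class ClusterDesign:
    """Cluster-simulation parameters.

    m: companions (W's) per cluster, so m_w = n_clusters * m in total.
    rho: exchangeable within-cluster correlation, in [0, 1).
    sigma_e: outcome noise standard deviation (outcome units).
    n: sample count.
    coefficients: main-effect sizes of the causal A's (default all 1).
    """

    m: int = 10
    rho: float = 0.5
    sigma_e: float = 5.0
    n: int = 500
    n_clusters: int = 25
    coefficients: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 1 or self.n_clusters < 1:
            raise ValueError("invalid design sizes")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1) for a positive-definite block")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        coefs = self.coefficients
        if coefs is None:
            coefs = tuple(1.0 for _ in range(self.n_clusters))
        coefs = tuple(float(c) for c in coefs)
        if len(coefs) != self.n_clusters:
            raise ValueError("need one coefficient per cluster")
        object.__setattr__(self, "coefficients", coefs)

    @property
    def m_w(self) -> int:
        return self.n_clusters * self.m

    @property
    def p(self) -> int:
        return self.n_clusters * (1 + self.m)


def simulate_cluster(design: ClusterDesign) -> ExpressionDataset:
    """Draw one dataset from the cluster design; truth flags mark the A's."""
    rng = np.random.default_rng(design.seed)
    n = design.n
    blocks, ids, truth = [], [], []
    a_cols = np.empty((n, design.n_clusters))
    for k in range(design.n_clusters):
        block = _exchangeable_block(rng, n, 1 + design.m, design.rho)
        blocks.append(block)
        a_cols[:, k] = block[:, 0]
        ids.append(f"A{k + 1:02d}")
        truth.append(True)
        for i in range(design.m):
            ids.append(f"A{k + 1:02d}_W{i + 1:02d}")
            truth.append(False)
    v = np.hstack(blocks)
    noise = design.sigma_e * rng.standard_normal(n)
    y = a_cols @ np.asarray(design.coefficients) + noise
    return ExpressionDataset(
        y=y,
        v=v,
        ids=ids,
        truth=np.asarray(truth),
        provenance=(
            f"cluster(m={design.m}, rho={design.rho}, sigma_e={design.sigma_e}, "
            f"n={design.n}, seed={design.seed})"
        ),
        noise=noise,
    )


@dataclass(frozen=True)
class GeneralDesign:
    """Correlation-matrix-driven simulation parameters.

    corr: p x p symmetric correlation matrix with unit diagonal (repaired to
        the nearest PSD matrix by eigenvalue clipping if needed, with a
        warning).
    causal_indices: columns entering the outcome (default: 20 columns evenly
        spread across p).
    outcome: "linear" or "polynomial". The polynomial form adds centered
        squares of the causal columns and the product of the first two to the
        linear part.
    noise_scale: outcome noise standard deviation.
    """

    corr: np.ndarray
    n: int = 500
    causal_indices: tuple[int, ...] | None = None
    coefficients: tuple[float, ...] | None = None
    outcome: str = "linear"
    noise_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        object.__setattr__(self, "corr", corr)
        p = corr.shape[0]
        idx = self.causal_indices
        if idx is None:
            k = min(20, p)
            idx = tuple(int(i) for i in np.linspace(0, p - 1, k).round())
        idx = tuple(int(i) for i in idx)
        if len(set(idx)) != len(idx) or any(not 0 <= i < p for i in idx):
            raise ValueError("causal indices must be distinct and within range")
        object.__setattr__(self, "causal_indices", idx)
        coefs = self.coefficients
        if coefs is None:
            coefs = tuple(1.0 for _ in idx)
        coefs = tuple(float(c) for c in coefs)
        if len(coefs) != len(idx):
            raise ValueError("need one coefficient per causal index")
        object.__setattr__(self, "coefficients", coefs)
        if self.outcome not in ("linear", "polynomial"):
            raise ValueError("outcome must be 'linear' or 'polynomial'")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")

    @property
    def p(self) -> int:
        return self.corr.shape[0]


def _psd_factor(corr: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Square-root factor of ``corr`` after PSD repair by eigenvalue clipping
    and re-normalization to unit diagonal."""
    w, u = np.linalg.eigh(corr)
    if w.min() < clip:
        warnings.warn(
            f"correlation matrix has eigenvalues down to {w.min():.3g}; "
            f"clipping at {clip:g} and renormalizing the diagonal"
        )
        w = np.clip(w, clip, None)
        repaired = (u * w) @ u.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        w, u = np.linalg.eigh(repaired)
        w = np.clip(w, 0.0, None)
    return u * np.sqrt(w)


def simulate_general(design: GeneralDesign) -> ExpressionDataset:
    """Draw one dataset from the general (correlation-matrix) design."""
    rng = np.random.default_rng(design.seed)
    factor = _psd_factor(design.corr)
    v = rng.standard_normal((design.n, design.p)) @ factor.T
    causal = list(design.causal_indices)
    a = v[:, causal]
    signal = a @ np.asarray(design.coefficients)
    if design.outcome == "polynomial":
        signal = signal + 0.5 * ((a**2) - 1.0).sum(axis=1)
        if len(causal) >= 2:
            signal = signal + 0.5 * a[:, 0] * a[:, 1]
    noise = design.noise_scale * rng.standard_normal(design.n)
    truth = np.zeros(design.p, dtype=bool)
    truth[causal] = True
    return ExpressionDataset(
        y=signal + noise,
        v=v,
        ids=[f"V{j + 1:04d}" for j in range(design.p)],
        truth=truth,
        provenance=(
            f"general(p={design.p}, n={design.n}, outcome={design.outcome}, "
            f"noise={design.noise_scale}, seed={design.seed})"
        ),
        noise=noise,
    )


def simulate_null(n: int, p: int, rho: float = 0.0, seed: int = 0) -> ExpressionDataset:
    """Covariates with exchangeable correlation ``rho``; outcome pure N(0,1)
    noise independent of every covariate."""
    if n < 1 or p < 1:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    v = _exchangeable_block(rng, n, p, rho)
    y = rng.standard_normal(n)
    return ExpressionDataset(
        y=y,
        v=v,
        ids=[f"V{j + 1:04d}" for j in range(p)],
        truth=np.zeros(p, dtype=bool),
        provenance=f"null(n={n}, p={p}, rho={rho}, seed={seed})",
        noise=y.copy(),
    )


def synthetic_expression_corr(
    p: int,
    seed: int = 0,
    n_factors: int = 3,
    loading_range: tuple[float, float] = (0.62, 0.82),
) -> np.ndarray:
    """Synthetic expression-style correlation matrix.

    A signed ``n_factors``-factor structure: column j has loading vector
    ``r_j * d_j`` with ``d_j`` uniform on the sphere and magnitude ``r_j``
    drawn from ``loading_range``, plus an idiosyncratic variance filling the
    unit diagonal. With three factors and the default magnitudes the absolute
    off-diagonal correlations have quartiles near (0.16, 0.26, 0.37), the
    pattern of tightly co-expressed gene panels; signs are mixed, so marginal
    associations of causal columns can be masked or inflated by their
    correlates.
    """
    if p < 2:
        raise ValueError("need at least two variables")
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((p, n_factors))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    magnitude = rng.uniform(*loading_range, size=p)
    loadings = directions * magnitude[:, None]
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    return corr
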