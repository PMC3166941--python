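"""Shared-Gram cross-validated lasso for the per-variable confounding fits.

The VIM pipeline fits ``g(W) ~ E(A | W)`` once per variable, and every fit
uses (nearly) the same design matrix: the dataset's variable matrix minus one
column. Refitting a cross-validated lasso from scratch p times recomputes the
same fold Gram matrices p times. This engine computes the per-fold Gram
matrices of the full matrix once per dataset and hands submatrix views to
scikit-learn's ``lasso_path`` (``precompute=Gram``, ``Xy`` given), which makes
each per-variable fit a pure coordinate-descent problem.

The produced fits agree numerically with ``LassoCV`` run with the same
contiguous fold structure and alpha grid (asserted in the test suite).

An optional sure-independence-style pre-screen keeps only the ``screen``
candidate columns most correlated with the target before the lasso; columns
with negligible correlation receive zero coefficients from the lasso anyway,
so the screen changes little while bounding the per-fit cost.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import lasso_path

__all__ = ["SharedLassoCVEngine"]


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    """Fold index blocks identical to sklearn's unshuffled KFold."""
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


class SharedLassoCVEngine:
    """Per-dataset context for fast repeated CV-lasso fits of one column on
    a subset of the others."""

    def __init__(
        self,
        v: np.ndarray,
        folds: int = 5,
        n_alphas: int = 20,
        eps: float = 1e-2,
        tol: float = 1e-3,
        max_iter: int = 3000,
        screen: int | None = None,
    ) -> None:
        v = np.asarray(v, dtype=float)
        if v.ndim != 2:
            raise ValueError("v must be a matrix")
        n, p = v.shape
        if n < folds:
            raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
        self.v = v
        self.n, self.p = n, p
        self.folds = folds
        self.n_alphas = n_alphas
        self.eps = eps
        self.tol = tol
        self.max_iter = max_iter
        self.screen = screen

        self._fold_idx = _contiguous_folds(n, folds)
        # Raw (uncentered) per-fold Grams; the train Gram of fold f is the
        # total minus the fold's own contribution.
        self._fold_gram = []
        self._fold_sums = []
        for idx in self._fold_idx:
            vf = v[idx]
            self._fold_gram.append(vf.T @ vf)
            self._fold_sums.append(vf.sum(axis=0))
        self._gram = sum(self._fold_gram)
        self._sums = v.sum(axis=0)
        self._corr: np.ndarray | None = None

    @property
    def corr(self) -> np.ndarray:
        """Pearson correlation matrix of the columns (zero-variance columns
        get zero correlations)."""
        if self._corr is None:
            n = self.n
            mu = self._sums / n
            cov = self._gram / n - np.outer(mu, mu)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = cov / np.outer(sd, sd)
            corr[~np.isfinite(corr)] = 0.0
            np.clip(corr, -1.0, 1.0, out=corr)
            np.fill_diagonal(corr, 1.0)
            self._corr = corr
        return self._corr

    def _screened(self, j: int, w: np.ndarray) -> np.ndarray:
        if self.screen is None or w.size <= self.screen:
            return w
        strength = np.abs(self.corr[j, w])
        keep = np.argsort(-strength, kind="stable")[: self.screen]
        return np.sort(w[keep])

    def fit_g(self, j: int, w_indices) -> tuple[np.ndarray, int]:
        """CV-lasso fit of column ``j`` on columns ``w_indices``.

        Returns the in-sample fitted values and the number of candidate
        confounders actually offered to the lasso (after screening).
        """
        w = np.unique(np.asarray(w_indices, dtype=int))
        if j in w:
            raise ValueError("candidate confounders must exclude the target")
        a = self.v[:, j]
        w = self._screened(j, w)
        if w.size == 0:
            return np.full(self.n, a.mean()), 0

        n = self.n
        mu = self._sums / n
        sub = np.ix_(w, w)
        xy_full = self._gram[w, j] - n * mu[w] * mu[j]
        alpha_max = np.abs(xy_full).max() / n
        if alpha_max <= 0.0:
            return np.full(self.n, a.mean()), int(w.size)
        alphas = np.geomspace(alpha_max, alpha_max * self.eps, self.n_alphas)

        mse = np.zeros(self.n_alphas)
        for f, val_idx in enumerate(self._fold_idx):
            nt = n - val_idx.size
            sums_t = self._sums - self._fold_sums[f]
            mu_t = sums_t / nt
            gram_t = self._gram[sub] - self._fold_gram[f][sub]
            gram_tc = gram_t - nt * np.outer(mu_t[w], mu_t[w])
            xy_t = (
                (self._gram[w, j] - self._fold_gram[f][w, j])
                - nt * mu_t[w] * mu_t[j]
            )
            x_tc = np.asfortranarray(
                np.delete(self.v[:, w], val_idx, axis=0) - mu_t[w]
            )
            y_tc = np.delete(a, val_idx) - mu_t[j]
            _, coefs, _ = lasso_path(
                x_tc,
                y_tc,
                alphas=alphas,
                precompute=gram_tc,
                Xy=xy_t,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            pred = (self.v[val_idx][:, w] - mu_t[w]) @ coefs + mu_t[j]
            mse += ((a[val_idx][:, None] - pred) ** 2).mean(axis=0)
        mse /= self.folds

        best = int(np.argmin(mse))  # ties -> larger penalty (alphas descend)
        gram_c = self._gram[sub] - n * np.outer(mu[w], mu[w])
        x_c = np.asfortranarray(self.v[:, w] - mu[w])
        _, coefs, _ = lasso_path(
            x_c,
            a - mu[j],
            alphas=alphas[: best + 1],
            precompute=gram_c,
            Xy=xy_full,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        coef = coefs[:, -1]
        g = mu[j] + (self.v[:, w] - mu[w]) @ coef
        return g, int(w.size)
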