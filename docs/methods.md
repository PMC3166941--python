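# Methods

## Model and estimand

For a continuous outcome `Y`, a target variable `A` and its candidate
confounders `W`, the working model is the semiparametric regression

    Y = β·A + f(W) + e,

with `f` unrestricted. The estimand is `β`, the marginal effect of `A`
adjusted for `W` (equivalently Ψ(a) = β·a, the adjusted effect of level `a`
versus 0). Only linearity in `A` is assumed. `β` is *not* a causal effect
without further assumptions; it is used as a variable-importance index whose
virtue is that it discounts associations explained by other variables. The
screening rationale: a predictor built on (nearly) causal variables transfers
to data where the covariate joint distribution changed but the outcome
mechanism did not, while a predictor built on correlates does not.

## The two-stage estimator

**Stage 1 (initial fit).** Two routes:

* *univariate*: OLS of `Y` on `(1, A)`; `β₀` = slope, `Q⁰` = fitted line.
* *grand*: one cross-validated lasso `G(V) ≈ E(Y|V)` on all p variables,
  fitted once. For each target `A`, the offset `G(A=0)` (the grand prediction
  with the `A` column zeroed — exact for a linear model via
  `fitted − coef_A·A`) absorbs `f(W)` and the intercept, and
  `β₀ = Σ A(Y − G(A=0)) / Σ A²` is the no-intercept offset regression.
  No intercept: one inside the offset regression would double-count the
  intercept already inside `G`.

**Stage 2 (targeting).** With `g(W) ≈ E(A|W)`:

* clever covariate `c = A − g(W)`;
* fluctuation `ε = Σ r·c / Σ c²`, the no-intercept LS slope of the stage-1
  residuals `r = Y − Q⁰` on `c` (no intercept: `f(W)` already lives in `Q⁰`);
* update `β* = β₀ + ε`, `Q* = Q⁰ + ε·c`.

**Inference.** Efficient-influence-curve variance

    IC_i = c_i (Y_i − Q*_i) / (n⁻¹ Σ_j c_j²),      σ̂² = n⁻² Σ_i IC_i²,

`T = β*/σ̂` standard normal under `β = 0`; p-values are two-sided (the sign
of an importance is not prespecified). `β*` is doubly robust: consistent if
either `Q⁰` or `g` is consistent, and efficient when both are.

Degenerate cases are conventions, not crashes: `σ² = 0` with `β* = 0` gives
p = 1; `σ² = 0` with `β* ≠ 0` flags an infinite statistic with p = 0; a
clever covariate that is identically zero (A fully explained by W) raises a
dedicated error, which the pipeline converts to p = 1 plus a
`degenerate_covariate` flag so the table keeps one row per variable.

## Confounder selection

Candidates for `g` are the columns with `|Pearson cor(·, A)| < δ` (strict
inequality; ties at exactly δ are excluded; zero-variance columns are
excluded with a warning). The default universal cutoff is δ = 0.7 — adjusting
for near-collinear variables destabilizes the estimate, while independence
yields zero adjustment, so only the intermediate range matters.

The adaptive variant computes the targeted result on a grid of cutoffs
(default {0.1, …, 0.9}) and returns the largest δ whose p-value is below λ
(default 0.05, a fixed constant; choosing λ by cross-validation is out of
scope). Smaller λ never yields a larger δ*. When no δ qualifies, the
smallest-δ result is returned flagged `no_delta_qualified` rather than
dropped — screening needs a p-value for every variable. Identical confounder
sets across adjacent grid points are computed once and reused.

## Pipeline defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `initial` | grand-lasso | stage-1 route (or `univariate`) |
| `delta` | 0.7 | universal correlation cutoff for `g` candidates |
| `folds` | 10 | CV folds of every lasso (penalty minimizing CV MSE, glmnet-style geometric path) |
| `n_alphas`, `eps` | 50, 0.01 | penalty-path length and span |
| `g_screen` | None | optional cap on g-fit candidates (see below) |
| truncation | raw p < 0.05 | or FDR-adjusted threshold, or top-k |

Multiple testing uses Benjamini–Hochberg step-up adjustment
(`statsmodels.multipletests`). Ranks order by p ascending with ties broken by
column order (stable and documented); top-k keeps the smallest ranks.
Binary outcomes are accepted as linear-probability outcomes with a warning;
a logistic fluctuation is out of scope. All fits are deterministic:
contiguous CV folds, cyclic coordinate descent — identical inputs give
byte-identical output tables regardless of evaluation order.

## Computation: shared-Gram cross-validated lasso

Fitting `g` is one cross-validated lasso per variable, p per dataset, and
every fit's design matrix is the dataset matrix minus one column. The
pipeline therefore precomputes per-fold Gram matrices of the full matrix once
per dataset; each per-variable fit extracts the relevant Gram submatrix and
runs scikit-learn's `lasso_path` on it (`precompute=Gram`, `Xy` supplied),
choosing the penalty by K-fold CV MSE on a geometric path anchored at that
fit's own `alpha_max`. This is algebraically the same estimator as `LassoCV`
with unshuffled folds and agrees with it to coordinate-descent tolerance
(asserted in the tests); it is roughly an order of magnitude faster at
p ≈ 500.

For benchmark-scale runs the engine additionally applies a
sure-independence-style pre-screen: only the `g_screen` candidates most
correlated with `A` (default 100 in the benchmark configuration) enter the
lasso. Columns with negligible correlation receive zero lasso coefficients
anyway, so the screen is close to a no-op statistically while bounding the
per-fit cost; the library default (`g_screen=None`) fits on all selected
candidates.

## Synthetic-data generators

**Cluster design** (`ClusterDesign`): 25 independent blocks, each one causal
variable `A` plus `m` companions, jointly Gaussian with unit variances and
exchangeable within-block correlation ρ (sampled as
`√ρ·z_shared + √(1−ρ)·z_own`, exactly the closed-form covariance
`(1−ρ)I + ρ11ᵀ`); outcome `Y = Σ β_j A_j + e`, `e ~ N(0, σ_e²)`. Defaults:
m = 10 (so 275 columns), ρ = 0.5, σ_e = 5, n = 500, **all β_j = 1** — the
simplest main-effect model; note that with unit coefficients the univariate
screen suffers no masking, so it is at its strongest, and the benchmark
ratios are conservative for the targeted method. A testing set with a
different ρ but the same mechanism is obtained via `dataclasses.replace`
(coefficients live in the design). The generator stores its noise draw so
tests can reconstruct `Y` exactly from the flagged columns.

**General design** (`GeneralDesign`): rows multivariate normal under an
arbitrary symmetric correlation matrix (repaired to PSD by eigenvalue
clipping at 1e-8 and diagonal renormalization, with a warning); outcome
linear or polynomial (centered squares of the causal columns plus the product
of the first two) in 20 causal columns (default: evenly spaced), noise scale
3.0 — chosen once so that adjusted effects are individually detectable at
n = 500, the regime in which a targeted screen is meaningful.
`synthetic_expression_corr` supplies a signed three-factor correlation matrix
whose absolute off-diagonal quartiles sit near (0.16, 0.26, 0.37), mimicking
the pervasive moderate co-expression of a real expression panel; signed
loadings mean some causal columns are marginally masked, which is exactly
where adjustment helps.

**Null design**: exchangeable covariates, outcome independent N(0,1); used
for type-I-error calibration.

What the generators do *not* emulate: heavy-tailed or skewed expression
distributions, measurement error, batch effects, hub-gene or
block-diagonal-plus-factor correlation mixtures, and non-additive outcome
mechanisms beyond the fixed polynomial. Passing benchmarks here demonstrates
correct adjustment under Gaussian linear conditions, not performance on raw
microarray intensities.

## Benchmarks and problem sizes

One benchmark replicate: simulate training data (n = 500), screen with both
methods, truncate at raw p < 0.05 (the FDR rule is available but benchmarks
use raw p), fit the downstream predictor (MVR = OLS on the selected columns —
deliberately without internal selection; or cross-validated lasso) and score
the L2 risk on a fresh testing set of 5000 samples, either at the training ρ
("testing set (a)") or at ρ = 0.1 ("testing set (b)", distribution shift
with fixed mechanism). An empty selection falls back to the training-mean
predictor, flagged. MVR with ≥ n selected variables raises rather than
silently regularizing — that breakdown is a finding, not a bug. Ratios with
zero denominators are reported as NaN with the raw counts kept.

The shipped configuration of `scripts/acceptance.py` uses the grand-lasso
initial, g fit by CV lasso on *all* other variables (δ = 1.0), 5 CV folds, a
20-point penalty path, `g_screen=100`, 3 replicates per setting (5 at the two
settings used for the ratio summaries), n_test = 5000 — sizes chosen to make
a full ten-setting sweep a few minutes on one CPU. The test suite exercises
the same machinery at smaller sizes (e.g. the correlated-design check uses
p = 300, n = 400, five replicates).

## Known limitations

* Single fluctuation step only; no iterated targeting.
* Continuous outcomes; binary outcomes are treated as linear-probability
  with a warning (no logistic fluctuation).
* The influence-curve variance assumes the initial fit is not grossly
  overfit; aggressive stage-1 learners can make the test anti-conservative.
* Adjusting for companions correlated with `A` beyond ~0.7 costs substantial
  efficiency (the clever covariate shrinks); at exchangeable ρ = 0.9 the
  targeted screen recovers markedly fewer causal variables than the
  univariate one even though its false-positive control stays intact — the
  motivation for the cutoff and its adaptive version.
* λ for the adaptive cutoff is a fixed constant, not cross-validated.
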