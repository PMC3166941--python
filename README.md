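# tmlevim — targeted variable importance for expression-style data

`tmlevim` ranks and screens the variables of a high-dimensional dataset
(gene-expression matrices are the motivating case) by a *targeted* estimate of
each variable's adjusted effect on a continuous outcome, instead of the usual
per-gene univariate regression. Univariate screens evaluate every gene in
isolation, so genes that are merely correlated with causal ones flood the
candidate list; machine-learning fits predict well but give unstable variable
rankings. The targeted procedure combines the two: a flexible machine-learning
fit supplies the initial estimate, and a second, analytically targeted step
corrects it for each variable's confounders and equips it with a valid
standard error and p-value.

## The model and the algorithm

For each candidate variable (gene) `A`, with all remaining variables `W` as
potential confounders, the semiparametric regression model is

    Y = β·A + f(W),        Ψ(a) = β·a

where `f` is arbitrary; `β` is the adjusted marginal effect of `A` and serves
as its variable-importance measure. `β` is estimated in two stages
(a targeted maximum-likelihood update):

1. **Initial fit.** Either a univariate OLS of `Y` on `A`, or a single grand
   penalized fit `G(V) ≈ E(Y|V)` of the outcome on *all* variables, reused
   for every target via the offset regression `Y − G(A=0) ~ β·A`
   (no intercept), giving `β₀` and fitted values `Q⁰`.
2. **Targeting.** Fit the confounding mechanism `g(W) ≈ E(A|W)` (by default a
   cross-validated lasso on the variables with `|cor(·, A)| < δ`, δ = 0.7),
   form the clever covariate `c = A − g(W)`, regress the residuals `Y − Q⁰`
   on `c` without intercept to get the fluctuation `ε`, and update
   `β* = β₀ + ε`, `Q* = Q⁰ + ε·c`.

Inference comes from the efficient influence curve
`IC_i = c_i (Y_i − Q*_i) / mean(c²)`: `σ² = Σ IC_i² / n²`, `T = β*/σ` is
standard normal under `β = 0`, and two-sided p-values are
Benjamini–Hochberg-adjusted across variables. `β*` is **doubly robust** —
consistent when either the initial outcome fit or `g` is consistent. The
ranked table is truncated by a raw-p threshold, an FDR threshold, or top-k,
to produce the reduced candidate list. An adaptive variant (per-variable
cutoff `δ*`, the largest on a grid whose p-value stays below a threshold `λ`)
protects against over-adjustment inside highly correlated blocks.

## A worked example

`examples/02_screening_pipeline.py` simulates the package's cluster design —
25 causal variables, each inside a block of 10 companions correlated with it
at ρ = 0.5, outcome = sum of the causal variables plus N(0, 5²) noise,
n = 500 — and screens all 275 variables both ways:

```
dataset: 500 samples x 275 variables (25 causal)
targeted (TMLE-VIM)   :  33 selected, 21 true positives,  12 false positives
univariate (UR-VIM)   : 103 selected, 20 true positives,  83 false positives
```

Both screens keep ~20 of the 25 causal variables at p < 0.05, but the
univariate list drags in 83 correlated bystanders where the targeted list
admits 12 — the adjustment for `E(A|W)` is what removes them.
`examples/03_benchmark_downstream_prediction.py` shows what that is worth
downstream: fitting plain multivariate regression on each list and scoring it
on 5000 fresh samples gives a held-out L2 risk of 30.0 (targeted list) versus
34.8 (univariate list), a proportional risk reduction R_r ≈ 0.14 with
true-positive ratio R_A ≈ 1.0 and false-positive ratio R_W ≈ 0.12.

The other examples demonstrate the single-variable targeting step
(`01_targeted_effect_single_gene.py`: a naive slope of +2.55 is pulled back
to the true adjusted effect ≈ +1.0) and the adaptive cutoff
(`04_adaptive_cutoff.py`).

There is also a thin CLI:

```sh
tmlevim simulate --design cluster --m 10 --rho 0.5 --sigma-e 5 --n 500 \
    --seed 1 --out-matrix m.tsv --out-phenotype p.tsv
tmlevim run m.tsv p.tsv -o vim.tsv --initial grand-lasso --seed 1
tmlevim reduce vim.tsv --threshold 0.05
```

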