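"""The adaptive per-variable correlation cutoff.

For a variable embedded in a highly correlated block, adjusting for *all*
companions can destroy power (the clever covariate degenerates), while a
universal cutoff may adjust too little. The adaptive procedure tries a grid
of cutoffs delta and keeps the largest one whose targeted p-value stays below
lambda.
"""

from tmlevim import AdaptiveConfig, ClusterDesign, adaptive_delta, simulate_cluster
from tmlevim.estimators import LassoLearner, fit_univariate_initial

dataset = simulate_cluster(ClusterDesign(m=10, rho=0.8, sigma_e=2.0, n=400, seed=5))
j = 0  # a causal variable inside a rho = 0.8 block
initial = fit_univariate_initial(dataset.y, dataset.v[:, j])

config = AdaptiveConfig(delta_grid=(0.2, 0.4, 0.6, 0.8, 0.95), lam=0.05)
delta_star, result = adaptive_delta(
    dataset, j, config, initial, learner=LassoLearner(folds=5, n_alphas=20)
)
print(f"variable {dataset.ids[j]} (causal)")
print(f"chosen cutoff delta*  : {delta_star}")
print(f"confounders adjusted  : {result.n_confounders}")
print(f"beta* / p-value       : {result.beta_star:+.3f} / {result.p_value:.2e}")
print(f"flags                 : {result.flags or '(none)'}")
# delta* is the most aggressive adjustment that still leaves a detectable
# effect; smaller lambda would demand stronger evidence and pick smaller
# cutoffs (more protection against over-adjustment).
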