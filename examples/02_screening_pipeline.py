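"""Dimension reduction on a simulated expression-style dataset.

Simulates the cluster design (25 causal variables, each wrapped in a block of
correlated non-causal companions), screens all variables with the targeted
procedure and with plain univariate regression, truncates both lists at raw
p < 0.05, and compares the true/false positive counts.
"""

import numpy as np

from tmlevim import ClusterDesign, compute_all_vim, reduce_list, simulate_cluster, ur_vim
from tmlevim.pipeline import RunConfig

design = ClusterDesign(m=10, rho=0.5, sigma_e=5.0, n=500, seed=42)
dataset = simulate_cluster(design)
print(f"dataset: {dataset.n} samples x {dataset.p} variables "
      f"({int(dataset.truth.sum())} causal)")

config = RunConfig(initial="grand-lasso", delta=1.0, folds=5, n_alphas=20,
                   g_screen=100)
tmle_table = compute_all_vim(dataset, config)
ur_table = ur_vim(dataset)

truth = {dataset.ids[j] for j in np.flatnonzero(dataset.truth)}
for name, table in [("targeted (TMLE-VIM)", tmle_table), ("univariate (UR-VIM)", ur_table)]:
    ids = reduce_list(table, ("p", 0.05))
    tp = sum(1 for i in ids if i in truth)
    print(f"{name:22s}: {len(ids):3d} selected, {tp:2d} true positives, "
          f"{len(ids) - tp:3d} false positives")
# The targeted list keeps about as many causal variables while admitting far
# fewer correlated bystanders: that is the whole point of adjusting each
# variable for its confounders before ranking.
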