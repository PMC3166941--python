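"""What screening quality buys downstream: prediction risk on held-out data.

Runs two replicates of the cluster benchmark at rho = 0.5: screen with both
methods, fit multivariate linear regression (MVR) on each reduced list, and
measure L2 risk on a fresh testing set, plus the summary ratios
R_r (risk reduction), R_A (true-positive ratio) and R_W (false-positive
ratio).
"""

from tmlevim import ClusterDesign
from tmlevim.evaluate import benchmark
from tmlevim.pipeline import RunConfig

report = benchmark(
    [ClusterDesign(m=10, rho=0.5, sigma_e=5.0, n=500)],
    replicates=2,
    seed=1,
    vim_config=RunConfig(initial="grand-lasso", delta=1.0, folds=5,
                         n_alphas=20, g_screen=100),
    n_test=5000,
)
row = report.iloc[0]
print(f"UR-VIM   MVR risk (test a): {row.ur_risk_a_mean:7.2f}")
print(f"TMLE-VIM MVR risk (test a): {row.tmle_risk_a_mean:7.2f}")
print(f"R_r (risk reduction)      : {row.r_r_a_mean:+.3f}")
print(f"R_A (TP ratio)            : {row.r_a_mean:.3f}")
print(f"R_W (FP ratio)            : {row.r_w_mean:.3f}")
# R_W well below 1 with R_A near 1 means the targeted screen removed false
# positives without losing causal variables; the MVR risk gap is what that
# cleanup is worth to a predictor with no internal variable selection.
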