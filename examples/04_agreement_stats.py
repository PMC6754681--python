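"""Correlation interpretation and Bland-Altman agreement.

Computes a Pearson correlation with its magnitude and effect-size labels,
then reconstructs a full Bland-Altman analysis from published summary
numbers alone (mean difference 80.50, limits of agreement -92.7 to 253.7,
n=53): the confidence intervals around the bias and around each limit of
agreement follow from the recovered SD of differences.
"""

import numpy as np

from lexiscreen import bland_altman, bland_altman_from_summary, pearson_correlation

rng = np.random.default_rng(0)
x = rng.normal(size=53)
y = 0.45 * x + rng.normal(size=53)
res = pearson_correlation(x, y)
print(f"r={res.r:.2f} n={res.n} p={res.p_two_tailed:.4f} "
      f"[{res.hinkle_label}; effect size: {res.es_label}]")

summary = bland_altman_from_summary(
    mean_diff=80.50, loa_lower=-92.7, loa_upper=253.7, n=53
)
print(f"recovered SD of differences: {summary.sd_diff:.3f}")
print(f"CI of mean difference: {summary.ci_mean[0]:.4f} .. {summary.ci_mean[1]:.4f}")
print(f"CI of upper limit:     {summary.ci_loa_upper[0]:.4f} .. {summary.ci_loa_upper[1]:.4f}")
print(f"CI of lower limit:     {summary.ci_loa_lower[0]:.4f} .. {summary.ci_loa_lower[1]:.4f}")

# The same analysis from raw pairs also counts differences outside the
# limits of agreement:
a = rng.normal(100, 90, size=53)
b = rng.normal(18, 11, size=53)
full = bland_altman(a, b)
print(f"raw-data run: mean diff {full.mean_diff:.1f}, "
      f"LoA {full.loa_lower:.1f}..{full.loa_upper:.1f}, "
      f"outliers {full.n_outliers}")
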