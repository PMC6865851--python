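"""Univariate group statistics for candidate discriminators and confounders.

Two-group comparison with an automatic normality gate, three-group ANOVA
with Tukey-adjusted pairwise contrasts, a categorical test, and a
confounder screen of a metabolite feature against clinical covariates.
"""

import numpy as np

from chemoclass import (
    anova_tukey,
    categorical_test,
    compare_two_groups,
    confounder_screen,
)

rng = np.random.default_rng(0)

values = np.r_[rng.normal(1.0, 0.2, 34), rng.normal(0.8, 0.2, 74)]
labels = np.r_[np.zeros(34), np.ones(74)]
cmp = compare_two_groups(values, labels, method="auto")
print(f"Two-group ({cmp.method}): statistic = {cmp.statistic:.2f}, "
      f"p = {cmp.p_value:.2e}")

vals3 = np.r_[rng.normal(0, 1, 6), rng.normal(0.8, 1, 14), rng.normal(1.6, 1, 21)]
g3 = np.r_[np.zeros(6), np.ones(14), np.full(21, 2.0)]
a = anova_tukey(vals3, g3)
print(f"ANOVA over groups of 6/14/21: F{a.notes['df']} = {a.statistic:.2f}, "
      f"p = {a.p_value:.4f}")
worst = a.pairwise.loc[a.pairwise.p_adj.idxmin()]
print(f"  strongest Tukey contrast: group {worst.group_a:g} vs {worst.group_b:g}, "
      f"adjusted p = {worst.p_adj:.4f}")

cat = categorical_test([[3, 9], [14, 8]], method="auto")
print(f"2x2 table ({cat.method}): p = {cat.p_value:.4f}")

feature = rng.normal(size=40)
screen = confounder_screen(
    feature,
    labels_by_stratum={"immunotherapy": (rng.random(40) < 0.4).astype(int)},
    continuous_covariates={"age": rng.normal(45, 12, 40)},
)
print("Confounder screen:")
for _, row in screen.iterrows():
    print(f"  {row.covariate} ({row.method}): p = {row.p_value:.3f}, "
          f"significant = {row.significant}")
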