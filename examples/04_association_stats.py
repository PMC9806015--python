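"""Associations between quantitative and spatial descriptors.

Simulates per-patient features with a built-in monotone association, then
computes the Spearman correlation matrix, a recurrence-group comparison of
one spatial feature, and a chi-square test on a categorical contrast.
"""

import numpy as np
import pandas as pd

import spatialtme as st

rng = np.random.default_rng(0)
n = 200
b_density = rng.gamma(4.0, 500.0, n)  # CD20+ B-cell density, per mm^2
t_density = 0.6 * b_density + rng.gamma(3.0, 400.0, n)  # co-infiltrating T cells
treg_len = 60 + 2000 / np.sqrt(b_density) + rng.normal(0, 3, n)  # Treg spacing
features = pd.DataFrame(
    {"CD20_density_TS": b_density, "CD4_density_TS": t_density,
     "len_FOXP3_FOXP3": treg_len}
)

m = st.spearman_matrix(features)
print("Spearman rho:")
print(m.rho.round(2).to_string())

recurred = rng.random(n) < 1 / (1 + np.exp(-(treg_len - np.median(treg_len)) / 10))
stat, p = st.compare_groups(features["len_FOXP3_FOXP3"], np.where(recurred, "rec", "free"))
print(f"\nTreg-Treg mean connection length, recurred vs. recurrence-free: "
      f"U={stat:.0f}, p={p:.2e}")

high_b = features["CD20_density_TS"] > features["CD20_density_TS"].median()
table = pd.crosstab(high_b, recurred).to_numpy()
chi2, p_chi, test = st.chi_square(table)
print(f"high B-cell infiltration vs. recurrence ({test}): "
      f"chi2={chi2:.2f}, p={p_chi:.3f}")
print(
    "\nPositive rho between B- and T-cell densities reflects their simulated\n"
    "co-infiltration; the negative rho with Treg spacing mirrors denser\n"
    "infiltrates sitting closer together."
)
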