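"""Descriptive association statistics for quantitative and spatial features.

Spearman rank correlations (pairwise-complete, average ranks for ties)
relate cell-amount variables to spatial connection variables; group
differences in continuous features use the rank-sum / t-test for two
groups and the Kruskal-Wallis H test for more; categorical contrasts use
Pearson's chi-square, falling back to Fisher's exact test for sparse 2x2
tables. All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with per-pair sample sizes."""

    variables: list
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered variable pair."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append(
                    {"var1": a, "var2": b, "rho": self.rho.loc[a, b],
                     "p": self.p.loc[a, b], "n": self.n.loc[a, b]}
                )
        return pd.DataFrame(rows)


def spearman_matrix(features: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix of a feature table.

    Pairs with fewer than ``min_n`` complete observations, or involving a
    constant variable, are left missing.
    """
    cols = list(features.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        rho[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = features[cols[i]].notna().sum()
        for j in range(i + 1, k):
            sub = features[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < min_n:
                continue
            a, b = sub.iloc[:, 0], sub.iloc[:, 1]
            if a.nunique() < 2 or b.nunique() < 2:
                continue  # constant variable: rho undefined
            r, pv = sps.spearmanr(a, b)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(
        variables=cols,
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols),
    )


def compare_groups(values, group_labels, test: str = "auto"):
    """Compare a continuous variable across groups.

    ``test='auto'`` uses the Wilcoxon rank-sum (Mann-Whitney U) test for
    two groups and the Kruskal-Wallis H test for more; ``test='t'`` forces
    Welch's t-test (two groups only). Returns ``(statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test applies to exactly two groups")
        r = sps.ttest_ind(groups[0], groups[1], equal_var=False)
        return float(r.statistic), float(r.pvalue)
    if test not in ("auto", "ranksum", "kruskal"):
        raise ValueError(f"unknown test {test!r}")
    if len(groups) == 2 and test in ("auto", "ranksum"):
        r = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(r.statistic), float(r.pvalue)
    r = sps.kruskal(*groups)
    return float(r.statistic), float(r.pvalue)


def chi_square(table) -> tuple[float, float, str]:
    """Association test for a two-way contingency table of counts.

    Pearson's chi-square without continuity correction by default; a 2x2
    table with any expected cell below 5 switches to Fisher's exact test.
    Returns ``(statistic, p, test_name)`` (statistic is NaN for Fisher).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("expected a 2-way contingency table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.shape == (2, 2):
        expected = sps.contingency.expected_freq(t)
        if np.any(expected < 5):
            odds, p = sps.fisher_exact(t)
            return float("nan"), float(p), "fisher"
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), "chi2"
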