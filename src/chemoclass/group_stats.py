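"""Univariate group comparisons and the confounder stratification screen.

Continuous features: pooled-variance two-sample t-test or Mann-Whitney U for
two groups (``auto`` gates on Shapiro-Wilk normality at alpha = 0.05), one-way
ANOVA with Tukey HSD (Tukey-Kramer for unequal n) or Kruskal-Wallis for three
or more.  Categorical tables: Pearson chi-square (no continuity correction)
or Fisher's conditional exact test (2x2, two-sided by the point-probability
rule).  All tests are two-sided; p < 0.05 is a flagging convention, never an
input filter, and the confounder screen applies no multiplicity adjustment by
default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_two_groups",
    "anova_tukey",
    "kruskal_wallis",
    "categorical_test",
    "confounder_screen",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one statistical test with per-group summaries."""

    method: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame
    pairwise: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


def _split_groups(values, group_labels, min_n: int = 2):
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.size != group_labels.size:
        raise ValueError("values and group_labels must have the same length")
    labels = np.unique(group_labels)
    groups = [values[group_labels == g] for g in labels]
    for g, arr in zip(labels, groups):
        if arr.size < min_n:
            raise ValueError(f"group {g!r} has fewer than {min_n} observations")
    return labels, groups


def _summaries(labels, groups) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": labels,
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) for g in groups],
        }
    )


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all label assignments.

    Two-sidedness by distance of U from its null mean n1*n2/2; ties are
    handled naturally because the enumeration uses the observed pooled values.
    """
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * b.size / 2
    d_obs = abs(u_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(pooled.size), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= d_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def _mann_whitney_normal(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction, no continuity correction."""
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var == 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2) / np.sqrt(var)
    return float(u), float(2 * stats.norm.sf(abs(z)))


def compare_two_groups(values, group_labels, method: str = "auto") -> GroupComparison:
    """Two-group comparison of a continuous feature.

    ``t_test`` is the pooled-variance two-sample t (Welch via
    ``method="welch"``); ``mann_whitney`` uses exact enumeration when both
    groups have n <= 8 and the tie-corrected normal approximation otherwise.
    ``auto`` picks the t-test when both groups pass Shapiro-Wilk at
    alpha = 0.05 and records the gate outcome in ``notes``.
    """
    labels, groups = _split_groups(values, group_labels)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {len(labels)}")
    a, b = groups
    notes: dict = {}
    if method == "auto":
        try:
            if any(np.ptp(g) == 0 for g in groups):  # constant data: gate to rank test
                normal = False
            else:
                normal = all(stats.shapiro(g).pvalue >= ALPHA for g in groups)
        except ValueError:
            normal = False
        method = "t_test" if normal else "mann_whitney"
        notes["auto_choice"] = method
        notes["shapiro_gate_alpha"] = ALPHA

    if method in ("t_test", "welch"):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            statistic, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            statistic, p = stats.ttest_ind(a, b, equal_var=(method == "t_test"))
        name = method
    elif method == "mann_whitney":
        if a.size <= 8 and b.size <= 8:
            statistic, p = _mann_whitney_exact(a, b)
            notes["mann_whitney_mode"] = "exact"
        else:
            statistic, p = _mann_whitney_normal(a, b)
            notes["mann_whitney_mode"] = "normal_tie_corrected"
        name = "mann_whitney"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        method=name,
        statistic=float(statistic),
        p_value=float(min(max(p, 0.0), 1.0)) if np.isfinite(p) else float(p),
        group_summaries=_summaries(labels, groups),
        notes=notes,
    )


def anova_tukey(values, group_labels) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    F has (k - 1, N - k) degrees of freedom; pairwise p-values come from the
    studentized range distribution with Tukey-Kramer standard errors for
    unequal group sizes.
    """
    labels, groups = _split_groups(values, group_labels)
    k = len(labels)
    if k < 2:
        raise ValueError("at least two groups required")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between, df_within = k - 1, N - k
    msw = ssw / df_within
    if ssw == 0:
        f_stat, p = (np.inf, 0.0) if ssb > 0 else (0.0, 1.0)
    else:
        f_stat = (ssb / df_between) / msw
        p = float(stats.f.sf(f_stat, df_between, df_within))

    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if msw == 0:
            p_adj = 1.0 if diff == 0 else 0.0
            q_stat = 0.0 if diff == 0 else np.inf
        else:
            se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
            q_stat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_stat, k, df_within))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": diff,
                "q": q_stat,
                "p_adj": min(max(p_adj, 0.0), 1.0),
            }
        )
    return GroupComparison(
        method="anova_tukey",
        statistic=float(f_stat),
        p_value=float(p),
        group_summaries=_summaries(labels, groups),
        pairwise=pd.DataFrame(rows),
        notes={"df": (df_between, df_within)},
    )


def kruskal_wallis(values, group_labels) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with the chi-square (k-1 df) approximation."""
    labels, groups = _split_groups(values, group_labels, min_n=1)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return GroupComparison(
        method="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        group_summaries=_summaries(labels, groups),
        notes={"df": len(labels) - 1},
    )


def categorical_test(counts_table, method: str = "auto") -> GroupComparison:
    """Pearson chi-square or Fisher's exact test on a contingency table.

    ``auto`` picks Fisher for 2x2 tables with any expected cell < 5, chi-square
    otherwise; the choice is recorded.  Fisher's two-sided p sums the
    probabilities of all tables (given the margins) no more probable than the
    observed one.
    """
    table = np.asarray(counts_table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("counts_table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts_table must hold nonnegative integers")
        table = np.round(table).astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal row or column")

    expected = stats.contingency.expected_freq(table)
    notes: dict = {}
    if method == "auto":
        method = "fisher_exact" if (table.shape == (2, 2) and expected.min() < 5) else "chi_square"
        notes["auto_choice"] = method
        notes["min_expected_cell"] = float(expected.min())

    counts_df = pd.DataFrame(table)
    if method == "chi_square":
        res = stats.chi2_contingency(table, correction=False)
        return GroupComparison(
            method="chi_square",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_summaries=counts_df,
            notes={**notes, "df": int(res.dof)},
        )
    if method == "fisher_exact":
        if table.shape != (2, 2):
            raise ValueError("fisher_exact supports 2x2 tables only")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(
            method="fisher_exact",
            statistic=float(odds),
            p_value=float(p),
            group_summaries=counts_df,
            notes={**notes, "statistic_is": "odds_ratio"},
        )
    raise ValueError(f"unknown method {method!r}")


def confounder_screen(
    feature_values,
    labels_by_stratum: Mapping[str, np.ndarray] | None = None,
    continuous_covariates: Mapping[str, np.ndarray] | None = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Screen one feature against potential confounders.

    Binary covariates stratify the samples and the feature is compared across
    strata (``compare_two_groups`` with the auto method gate); continuous
    covariates are tested by Pearson and Spearman correlation.  Covariates
    whose strata are degenerate are reported as not evaluable rather than
    aborting.  No multiplicity adjustment by default; ``adjust="bh"`` adds a
    Benjamini-Hochberg column.
    """
    x = np.asarray(feature_values, dtype=float)
    rows = []
    for name, strat in (labels_by_stratum or {}).items():
        strat = np.asarray(strat)
        try:
            cmp = compare_two_groups(x, strat, method="auto")
            rows.append(
                {
                    "covariate": name,
                    "kind": "binary",
                    "method": cmp.method,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "evaluable": True,
                    "note": cmp.notes.get("auto_choice", ""),
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "covariate": name,
                    "kind": "binary",
                    "method": "",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "evaluable": False,
                    "note": str(exc),
                }
            )
    for name, cov in (continuous_covariates or {}).items():
        cov = np.asarray(cov, dtype=float)
        for label, fn in (("pearson", stats.pearsonr), ("spearman", stats.spearmanr)):
            try:
                if np.std(x) == 0 or np.std(cov) == 0:
                    raise ValueError("constant input")
                r, p = fn(x, cov)
                rows.append(
                    {
                        "covariate": name,
                        "kind": "continuous",
                        "method": label,
                        "statistic": float(r),
                        "p_value": float(p),
                        "evaluable": True,
                        "note": "",
                    }
                )
            except ValueError as exc:
                rows.append(
                    {
                        "covariate": name,
                        "kind": "continuous",
                        "method": label,
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "evaluable": False,
                        "note": str(exc),
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = (out["p_value"] < ALPHA).fillna(False)
        if adjust == "bh":
            mask = out["p_value"].notna()
            adj = np.full(len(out), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = stats.false_discovery_control(
                    out.loc[mask, "p_value"].to_numpy()
                )
            out["p_adjusted_bh"] = adj
    return out
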