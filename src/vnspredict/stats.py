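"""Group-comparison statistics: Mann-Whitney U, Cohen's d, FDR, categorical tests.

The feature panel is compared between responder (R50) and nonresponder
(NR50) groups with nonparametric rank tests; per-band nodal results form
one FDR family. Cohen's d uses the pooled-SD convention with n-1 weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Group sizes at or below which the exact Mann-Whitney null is used
#: (when the data are tie-free).
EXACT_N_MAX = 12


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midrank ties).

    Returns (U, p) with U the statistic of ``x``. The exact null
    distribution is used for small tie-free samples (n1 + n2 <= 12);
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= EXACT_N_MAX
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    return cohens_d_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def cohens_d_from_summary(m1, s1, n1, m2, s2, n2) -> float:
    """Cohen's d from group summaries, pooled SD with n-1 weighting."""
    pooled_var = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((m1 - m2) / np.sqrt(pooled_var))


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Benjamini-Yekutieli optional)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError(f"unsupported FDR method {method!r}")
    return multipletests(p, method=method)[1]


def categorical_test(table, seed: int = 0, n_monte_carlo: int = 20000) -> float:
    """Association p-value for a 2 x k contingency table of counts.

    Chi-square when every expected count is >= 5; otherwise Fisher's exact
    test for 2 x 2 tables, or a seeded Monte-Carlo Freeman-Halton style test
    (chi-square statistic under fixed margins) for wider tables.
    """
    table = np.asarray(table)
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = np.asarray(table, dtype=float)
        if (table < 0).any() or not np.allclose(table, np.round(table)):
            raise ValueError("table must hold non-negative integer counts")
        table = table.astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    if (expected >= 5).all():
        return float(sps.chi2_contingency(table, correction=False)[1])
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    # Monte-Carlo exact-style test for sparse 2 x k tables
    observed = float(sps.chi2_contingency(table, correction=False)[0])
    rng = np.random.default_rng(seed)
    dist = sps.random_table(row, col, seed=rng)
    draws = dist.rvs(n_monte_carlo)
    stats_mc = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1 + (stats_mc >= observed - 1e-12).sum()) / (1 + n_monte_carlo))


@dataclass
class GroupComparison:
    feature: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    u_statistic: float
    p_value: float
    p_adjusted: float
    cohens_d: float


def compare_feature_groups(
    features: pd.DataFrame,
    labels: pd.Series,
    group_1: str = "NR50",
    group_2: str = "R50",
    fdr_family: list[str] | None = None,
) -> pd.DataFrame:
    """Group-wise comparison table for continuous features.

    One row per feature: per-group mean +/- SD, Mann-Whitney U and p,
    FDR-adjusted p (over ``fdr_family`` columns, default all), Cohen's d
    (group_1 minus group_2).
    """
    mask_1 = labels == group_1
    mask_2 = labels == group_2
    rows = []
    for col in features.columns:
        x = features.loc[mask_1, col].to_numpy(dtype=float)
        y = features.loc[mask_2, col].to_numpy(dtype=float)
        u, p = mann_whitney_u(x, y)
        try:
            d = cohens_d(x, y)
        except ValueError:
            d = np.nan
        rows.append(
            {
                "feature": col,
                f"{group_1}_mean": x.mean(), f"{group_1}_sd": x.std(ddof=1),
                f"{group_1}_n": x.size,
                f"{group_2}_mean": y.mean(), f"{group_2}_sd": y.std(ddof=1),
                f"{group_2}_n": y.size,
                "U": u, "p": p, "cohens_d": d,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    family = fdr_family if fdr_family is not None else list(out.index)
    adj = pd.Series(np.nan, index=out.index)
    adj.loc[family] = fdr_adjust(out.loc[family, "p"].to_numpy())
    out["p_fdr"] = adj
    return out.reset_index()
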