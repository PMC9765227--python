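"""Nonparametric group comparisons: Kruskal-Wallis, Dunn's post hoc and
Mann-Whitney U, each with Benjamini-Hochberg adjustment where multiple
comparisons arise.  All tests are two-sided.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .energetics import CorrelationResult


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def kruskal_wallis(groups: list) -> CorrelationResult:
    """Kruskal-Wallis rank sum test across >= 2 groups (tie-corrected).

    Degenerate input (every value identical) returns statistic 0 with
    p = 1 under the "degenerate" method label instead of erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return CorrelationResult(0.0, 1.0, n_total, "kruskal-wallis-degenerate")
    res = stats.kruskal(*groups)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n_total,
                             "kruskal-wallis")


def dunn_posthoc(groups: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's post hoc test on mean ranks, BH-adjusted across all pairs.

    z for groups i, j is ``(Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) *
    (1/n_i + 1/n_j))`` where T = sum(t^3 - t) / (12 (N - 1)) corrects for
    ties in the pooled ranking.  Returns one row per unordered pair with
    z, raw p and BH-adjusted p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    offset = 0
    for n in sizes:
        mean_ranks.append(ranks[offset : offset + n].mean())
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        denom = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / denom
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def mann_whitney_bh(
    focal, others: list, labels: list[str] | None = None
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of a focal group vs each other group.

    Exact enumeration when both samples have <= 20 observations, normal
    approximation otherwise; BH adjustment across the list of comparisons.
    """
    focal = np.asarray(focal, dtype=float)
    if len(focal) == 0:
        raise ValueError("focal group is empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(others))]
    rows = []
    for label, other in zip(labels, others):
        other = np.asarray(other, dtype=float)
        if len(other) == 0:
            raise ValueError(f"comparison group {label!r} is empty")
        method = "exact" if max(len(focal), len(other)) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(focal, other, alternative="two-sided",
                                 method=method)
        rows.append({"group": label, "U": float(res.statistic),
                     "p": float(res.pvalue), "n_focal": len(focal),
                     "n_other": len(other), "method": method})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def pearson(x, y) -> CorrelationResult:
    """Two-sided Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x),
                             "pearson")
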