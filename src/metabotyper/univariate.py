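"""Per-metabolite between-cluster comparisons with normality-driven test choice.

For each variable, per-group normality is checked with the
Kolmogorov-Smirnov test using Lilliefors critical values (parameters are
estimated from the sample, so the plain KS null is anti-conservative).
Two groups: Welch t-test when all groups pass normality, Mann-Whitney U
otherwise.  Three or more groups: Welch ANOVA with Dunnett's T3-style
pairwise post hoc (unequal variances) when normal, Kruskal-Wallis with
Dunn's Bonferroni-adjusted pairwise comparisons otherwise.  Pairwise
significance is summarized as compact letter codes: groups sharing a
letter are not significantly different.  All tests are two-sided and
evaluated at alpha = 0.05 (no multiplicity correction across metabolites
by default; Benjamini-Hochberg is available as an option).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .cluster import Partition
from .data_model import MetaboliteTable

ALPHA = 0.05
MIN_GROUP_N = 3


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return False  # degenerate, treat as non-normal
    if len(x) < 4:
        return True  # too few observations to reject normality
    _, p = lilliefors(x, dist="norm")
    return p > alpha


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    pairwise_p: pd.DataFrame | None = None  # groups x groups, post hoc
    letters: dict | None = None


def choose_and_compare_two(x1, x2, alpha: float = ALPHA) -> TestResult:
    """Welch t-test if both groups pass the normality check, else Mann-Whitney U."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    if len(x1) < MIN_GROUP_N or len(x2) < MIN_GROUP_N:
        raise ValueError(f"each group needs n >= {MIN_GROUP_N}")
    if _is_normal(x1, alpha) and _is_normal(x2, alpha):
        stat, p = sps.ttest_ind(x1, x2, equal_var=False)
        return TestResult("welch-t", float(stat), float(p))
    stat, p = sps.mannwhitneyu(x1, x2, alternative="two-sided")
    return TestResult("mann-whitney", float(stat), float(p))


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA (F*, p)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(vars_ == 0):
        vars_ = np.where(vars_ == 0, 1e-12, vars_)
    w = ns / vars_
    mw = (w * means).sum() / w.sum()
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    b = 2.0 * (k - 2) / (k**2 - 1) * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
    f = a / (1 + b)
    df2 = (3.0 / (k**2 - 1) * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()) ** -1
    p = float(sps.f.sf(f, k - 1, df2))
    return float(f), p


def dunnett_t3_pairwise(groups: list[np.ndarray]) -> pd.DataFrame:
    """Unequal-variance pairwise comparisons (T3-style).

    Pairwise Welch t statistics with Welch degrees of freedom, Sidak
    adjusted over the number of pairs (a conservative surrogate for the
    studentized-maximum-modulus reference distribution).
    """
    k = len(groups)
    out = np.full((k, k), np.nan)
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        _, p_raw = sps.ttest_ind(groups[i], groups[j], equal_var=False)
        p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** n_pairs
        out[i, j] = out[j, i] = p_adj
    return pd.DataFrame(out)


def dunn_pairwise(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons, Bonferroni adjusted."""
    k = len(groups)
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    idx = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(k)]
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    out = np.full((k, k), np.nan)
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out[i, j] = out[j, i] = min(p * n_pairs, 1.0)
    return pd.DataFrame(out)


def letters_from_pairwise(pairwise_p: pd.DataFrame, alpha: float = ALPHA) -> dict[int, str]:
    """Compact letter display from a pairwise p-value matrix.

    Greedy insert-and-absorb: groups sharing a letter are not significantly
    different at alpha.  Keys are group positions 0..k-1.
    """
    k = pairwise_p.shape[0]
    p = pairwise_p.to_numpy()
    differ = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i != j and np.isfinite(p[i, j]):
                differ[i, j] = p[i, j] < alpha
    # insert-and-absorb: start from one all-groups set; every significant
    # pair splits the sets containing both; absorb subsets
    letter_sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not differ[i, j]:
                continue
            new_sets: list[set[int]] = []
            for s in letter_sets:
                if i in s and j in s:
                    new_sets.extend([s - {i}, s - {j}])
                else:
                    new_sets.append(s)
            letter_sets = [
                s for a, s in enumerate(new_sets)
                if s and not any(s < t or (s == t and a > b) for b, t in enumerate(new_sets) if a != b)
            ]
    letter_sets.sort(key=min)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in range(k)}
    for li, s in enumerate(letter_sets):
        for g in sorted(s):
            out[g] += alphabet[li]
    return out


def choose_and_compare_k(groups: list[np.ndarray], alpha: float = ALPHA) -> TestResult:
    """Omnibus + post hoc for k >= 3 groups with normality-driven choice.

    All normal: Welch ANOVA with T3-style pairwise post hoc; otherwise
    Kruskal-Wallis with Dunn-Bonferroni pairwise comparisons.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need k >= 3 groups")
    if any(len(g) < MIN_GROUP_N for g in groups):
        raise ValueError(f"each group needs n >= {MIN_GROUP_N}")
    if all(_is_normal(g, alpha) for g in groups):
        f, p = welch_anova(groups)
        pw = dunnett_t3_pairwise(groups)
        name = "welch-anova+t3"
    else:
        f, p = sps.kruskal(*groups)
        pw = dunn_pairwise(groups)
        name = "kruskal-wallis+dunn"
    letters = letters_from_pairwise(pw, alpha)
    return TestResult(name, float(f), float(p), pw, letters)


def levene(groups: list[np.ndarray]) -> float:
    """Levene's homoscedasticity test (mean-centered variant); returns p."""
    if len(groups) < 2:
        raise ValueError("Levene's test needs k >= 2 groups")
    _, p = sps.levene(*[np.asarray(g, float) for g in groups], center="mean")
    return float(p)


def cluster_summary(
    table: MetaboliteTable,
    partition: Partition,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Between-cluster comparison table for every metabolite plus the
    sulfate and glucuronide sums.

    One row per variable x cluster with N, mean, SD, the chosen test, its
    p-value, a significance flag at alpha and (for >= 3 clusters) compact
    letter codes.  Variables where any cluster falls below the minimum
    group size abstain from testing (reported with blank test fields).
    With ``fdr`` set, p-values are Benjamini-Hochberg adjusted across
    variables (off by default).
    """
    if partition.n != table.n_samples:
        raise ValueError("partition does not cover all samples")
    v = table.values.copy()
    if not table.aggregated:
        sulf = table.columns_of_class("sulfate") + table.columns_of_class("methoxy-sulfate")
        gluc = table.columns_of_class("glucuronide")
        v["SUM sulfate conjugates"] = table.values[sulf].sum(axis=1, skipna=False)
        v["SUM glucuronide conjugates"] = table.values[gluc].sum(axis=1, skipna=False)
    labels = partition.labels
    cluster_ids = sorted(set(labels))
    rows = []
    pvals: list[float | None] = []
    for var in v.columns:
        col = v[var].to_numpy(dtype=float)
        groups = [col[labels == c] for c in cluster_ids]
        groups = [g[~np.isnan(g)] for g in groups]
        test_name, p, letters = "", np.nan, None
        if len(cluster_ids) >= 2 and all(len(g) >= MIN_GROUP_N for g in groups):
            if len(cluster_ids) == 2:
                res = choose_and_compare_two(groups[0], groups[1], alpha)
            else:
                res = choose_and_compare_k(groups, alpha)
            test_name, p, letters = res.test, res.p_value, res.letters
        pvals.append(p)
        for ci, c in enumerate(cluster_ids):
            rows.append(
                {
                    "variable": var,
                    "cluster_id": c,
                    "N": len(groups[ci]),
                    "mean": groups[ci].mean() if len(groups[ci]) else np.nan,
                    "sd": groups[ci].std(ddof=1) if len(groups[ci]) > 1 else np.nan,
                    "test": test_name,
                    "p": p,
                    "letters": letters[ci] if letters else "",
                }
            )
    report = pd.DataFrame(rows)
    if fdr:
        finite = report["p"].notna()
        # adjust once per variable, then broadcast back to cluster rows
        per_var = report.loc[finite].drop_duplicates("variable")[["variable", "p"]]
        if len(per_var):
            adj = multipletests(per_var["p"], method="fdr_bh")[1]
            mapping = dict(zip(per_var["variable"], adj))
            report.loc[finite, "p"] = report.loc[finite, "variable"].map(mapping)
    report["significant"] = report["p"] < alpha
    return report
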