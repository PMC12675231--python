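"""Descriptive and nonparametric inferential statistics across phenotypes.

Normality gating (Shapiro–Wilk), Kruskal–Wallis with tie correction,
Dunn's post hoc z-tests, Bonferroni / Benjamini–Hochberg multiplicity
control, pooled-SD Cohen's d, Spearman correlation matrices and
cutoff-prevalence tables.  Ranking uses average ranks for ties throughout;
missingness is handled listwise within each test and pairwise-complete for
correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normality_gate",
    "kruskal_wallis",
    "dunn_posthoc",
    "adjust_pvalues",
    "spearman_matrix",
    "prevalence_table",
    "cohens_d",
    "compare_groups",
]


@dataclass
class NormalityResult:
    statistic: float
    p: float
    is_normal: bool
    degenerate: bool = False


def normality_gate(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk test; ``is_normal`` means p > alpha.

    Constant vectors are flagged degenerate (W undefined) rather than raised.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if v.size > 5000:
        raise ValueError("Shapiro–Wilk is calibrated for n ≤ 5000; subsample first")
    if np.ptp(v) == 0:
        return NormalityResult(statistic=np.nan, p=np.nan, is_normal=False, degenerate=True)
    w, p = stats.shapiro(v)
    return NormalityResult(statistic=float(w), p=float(p), is_normal=bool(p > alpha))


def _rank_and_tie_term(values: np.ndarray):
    ranks = stats.rankdata(values)  # average ranks for ties
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def kruskal_wallis(values, group_labels):
    """Tie-corrected Kruskal–Wallis H with the χ²(k−1) reference.

    Returns ``(H, p)``.  An all-identical sample is degenerate: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    n = len(values)
    ranks, tie_sum = _rank_and_tie_term(values)
    rank_by_group = [ranks[labels == g] for g in pd.unique(labels)]
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / len(r) for r in rank_by_group) - 3 * (n + 1)
    correction = 1.0 - tie_sum / (n**3 - n)
    h /= correction
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df))
    return float(h), p


@dataclass
class DunnPair:
    group_a: str
    group_b: str
    z: float
    p: float
    p_adjusted: float
    median_diff: float
    cohens_d: float


def dunn_posthoc(values, group_labels, adjust: str = "bonferroni") -> list:
    """Dunn's rank-based pairwise z-tests after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j) )
    with T = Σ(t³−t) over tie groups.  Adjustment: "bonferroni" or "bh".
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if any(np.sum(labels == g) == 0 for g in names):
        raise ValueError("every group must be nonempty")
    n = len(values)
    ranks, tie_sum = _rank_and_tie_term(values)
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    results = []
    raw_p = []
    for a, b in itertools.combinations(names, 2):
        ra, rb = ranks[labels == a], ranks[labels == b]
        va, vb = values[labels == a], values[labels == b]
        z = (ra.mean() - rb.mean()) / np.sqrt(var_term * (1 / len(ra) + 1 / len(rb)))
        p = 2 * stats.norm.sf(abs(z))
        d = cohens_d(va, vb) if min(len(va), len(vb)) >= 2 else np.nan
        results.append(
            DunnPair(
                group_a=str(a), group_b=str(b), z=float(z), p=float(p),
                p_adjusted=np.nan,
                median_diff=float(np.median(va) - np.median(vb)),
                cohens_d=d,
            )
        )
        raw_p.append(p)
    adjusted = adjust_pvalues(raw_p, method=adjust)
    for res, padj in zip(results, adjusted):
        res.p_adjusted = float(padj)
    return results


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg ("bh") adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def spearman_matrix(table: pd.DataFrame, variables) -> tuple:
    """Pairwise-complete Spearman rho and p (t-approximation).

    Returns ``(rho, p)`` DataFrames.  Constant columns yield NaN entries
    (undefined rank correlation) rather than an error.
    """
    variables = list(variables)
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
        for j in range(i + 1, k):
            a = table[variables[i]].to_numpy(dtype=float)
            b = table[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 4:
                raise ValueError(
                    f"fewer than 4 complete pairs for {variables[i]}–{variables[j]}"
                )
            if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                continue  # undefined, left as NaN
            r, p = stats.spearmanr(a[ok], b[ok])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=variables, columns=variables),
        pd.DataFrame(pmat, index=variables, columns=variables),
    )


def prevalence_table(table: pd.DataFrame, cutoffs: dict) -> pd.DataFrame:
    """Counts and percentages of participants at or above per-subscale cutoffs."""
    rows = []
    n = len(table)
    for subscale, cutoff in cutoffs.items():
        if subscale not in table.columns:
            raise KeyError(f"unknown subscale {subscale!r}")
        scores = table[subscale].to_numpy(dtype=float)
        count = int(np.sum(scores >= cutoff))
        rows.append(
            {
                "subscale": subscale,
                "cutoff": cutoff,
                "count": count,
                "percent": 100.0 * count / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cohens_d(group_a, group_b) -> float:
    """Pooled-SD standardized mean difference (a minus b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return np.nan  # degenerate: no within-group spread
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def compare_groups(table: pd.DataFrame, variables, group_col: str,
                   adjust: str = "bonferroni") -> pd.DataFrame:
    """Kruskal–Wallis + Dunn pairs for each variable; tidy one-row-per-pair table.

    The KW p-values across variables additionally receive a BH-adjusted q.
    """
    kw_rows = []
    pair_rows = []
    for var in variables:
        sub = table[[var, group_col]].dropna()
        h, p = kruskal_wallis(sub[var], sub[group_col])
        kw_rows.append({"variable": var, "H": h, "kw_p": p})
        for pair in dunn_posthoc(sub[var], sub[group_col], adjust=adjust):
            pair_rows.append(
                {
                    "variable": var,
                    "group_a": pair.group_a,
                    "group_b": pair.group_b,
                    "z": pair.z,
                    "p": pair.p,
                    "p_adjusted": pair.p_adjusted,
                    "median_diff": pair.median_diff,
                    "cohens_d": pair.cohens_d,
                }
            )
    kw = pd.DataFrame(kw_rows)
    kw["kw_q"] = adjust_pvalues(kw["kw_p"].to_numpy(), method="bh")
    kw.attrs["fdr_family_size"] = len(kw)
    pairs = pd.DataFrame(pair_rows)
    return kw.merge(pairs, on="variable", how="left")
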