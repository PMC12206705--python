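"""Group-comparison statistical screen.

Per feature: Kolmogorov–Smirnov normality check, Levene homoscedasticity,
tie-corrected Kruskal–Wallis omnibus test with the rank epsilon-squared
effect size (ϵ² = H/(n−1)), Dunn pairwise post-hoc tests with Bonferroni
adjustment, and Kendall tau-b correlation against potential confounders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWResult",
    "PosthocResult",
    "NormalityResult",
    "VarianceResult",
    "CorrelationResult",
    "kruskal_wallis",
    "epsilon_squared",
    "dunn_bonferroni",
    "ks_normality",
    "levene",
    "kendall_tau_b",
    "feature_screen",
]


@dataclass(frozen=True)
class KWResult:
    feature_name: str
    n_total: int
    df: int
    H: float
    epsilon_squared: float
    p_value: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    z: float
    p_adjusted: float


@dataclass(frozen=True)
class NormalityResult:
    D: float
    p_value: float


@dataclass(frozen=True)
class VarianceResult:
    W: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    tau_b: float
    p_value: float


def _clean_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError("every group must contain at least one non-missing value")
        cleaned.append(arr)
    return cleaned


def epsilon_squared(H: float, n: int) -> float:
    """Rank effect size for the Kruskal–Wallis test: ϵ² = H / (n − 1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if H < 0:
        raise ValueError("H must be >= 0")
    return H / (n - 1)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], feature_name: str = ""
) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p and ϵ² effect size.

    When every pooled value is identical the tie correction degenerates;
    by convention H = 0, p = 1 (with a warning) instead of an error.
    """
    cleaned = _clean_groups(groups)
    n = sum(g.size for g in cleaned)
    df = len(cleaned) - 1
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; returning H = 0, p = 1")
        return KWResult(feature_name, n, df, 0.0, 0.0, 1.0)
    H, p = sps.kruskal(*cleaned)
    return KWResult(feature_name, n, df, float(H), epsilon_squared(float(H), n), float(p))


def dunn_bonferroni(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[PosthocResult]:
    """Dunn pairwise z tests on pooled tie-corrected ranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j)) with the tie
    term T = Σ(t³ − t) / (12(N − 1)); p_adjusted = min(1, m · p_raw) with m
    the number of pairs.
    """
    cleaned = _clean_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(cleaned))]
    if len(labels) != len(cleaned):
        raise ValueError("labels length mismatch")
    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks, sizes = [], []
    start = 0
    for g in cleaned:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(list(combinations(range(len(cleaned)), 2)))
    results = []
    for i, j in combinations(range(len(cleaned)), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_raw = 2.0 * sps.norm.sf(abs(z))
        results.append(
            PosthocResult((labels[i], labels[j]), float(z), min(1.0, m * p_raw))
        )
    return results


def ks_normality(x: Sequence[float], standardize: bool = False) -> NormalityResult:
    """One-sample Kolmogorov–Smirnov test against the standard normal.

    By default the raw (unstandardized) values are compared to N(0, 1): for
    non-negative-valued features this yields D ≥ 0.5, the regime the screen
    reports.  ``standardize=True`` gives a Lilliefors-style variant that
    centers and scales by the sample moments first (its p-value is then only
    approximate).
    """
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    if standardize:
        sd = arr.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance; cannot standardize")
        arr = (arr - arr.mean()) / sd
    D, p = sps.kstest(arr, "norm")
    return NormalityResult(float(D), float(p))


def levene(groups: Sequence[Sequence[float]]) -> VarianceResult:
    """Mean-centered Levene test of homogeneity of variance."""
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2 or any(g.size < 2 for g in cleaned):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.all(g == cleaned[0][0]) for g in cleaned):
        return VarianceResult(0.0, 1.0)
    W, p = sps.levene(*cleaned, center="mean")
    return VarianceResult(float(W), float(p))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Kendall rank correlation (tau-b) with two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise ValueError("need at least 2 pairs")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    tau, p = sps.kendalltau(xa[keep], ya[keep], variant="b")
    return CorrelationResult(float(tau), float(p))


def feature_screen(
    table: pd.DataFrame,
    group_col: str = "group",
    posthoc: str = "significant",
    alpha: float = 0.05,
    bh_qvalues: bool = False,
) -> pd.DataFrame:
    """Run the full per-feature screen on a feature table.

    Parameters
    ----------
    table:
        Feature table with one numeric column per feature plus ``group_col``.
    posthoc:
        ``"significant"`` (Dunn only when omnibus p < alpha, as published),
        ``"always"`` or ``"never"``.
    bh_qvalues:
        Append Benjamini–Hochberg q-values across the feature screen
        (off by default — the published screen adjusts only within post-hocs).

    Returns one row per feature with D, W, H, df, epsilon², p and one
    adjusted-p column per group pair.
    """
    if posthoc not in ("significant", "always", "never"):
        raise ValueError("posthoc must be 'significant', 'always' or 'never'")
    group_labels = list(dict.fromkeys(table[group_col]))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    feature_cols = [c for c in table.columns if c != group_col]
    pair_names = [f"{a}_vs_{b}" for a, b in combinations(group_labels, 2)]
    rows = []
    for feat in feature_cols:
        groups = [
            table.loc[table[group_col] == g, feat].to_numpy(dtype=float)
            for g in group_labels
        ]
        groups = [g[~np.isnan(g)] for g in groups]
        if any(g.size == 0 for g in groups):
            rows.append({"feature": feat})
            continue
        pooled = np.concatenate(groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = ks_normality(pooled) if pooled.size >= 2 else None
            var = levene(groups) if all(g.size >= 2 for g in groups) else None
            kw = kruskal_wallis(groups, feature_name=feat)
        row = {
            "feature": feat,
            "D": norm.D if norm else np.nan,
            "W": var.W if var else np.nan,
            "n": kw.n_total,
            "df": kw.df,
            "H": kw.H,
            "epsilon_squared": kw.epsilon_squared,
            "p": kw.p_value,
        }
        run_posthoc = posthoc == "always" or (
            posthoc == "significant" and kw.p_value < alpha
        )
        if run_posthoc:
            for res in dunn_bonferroni(groups, labels=group_labels):
                row[f"{res.pair[0]}_vs_{res.pair[1]}"] = res.p_adjusted
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    for col in pair_names:
        if col not in out.columns:
            out[col] = np.nan
    if bh_qvalues:
        p = out["p"].to_numpy(dtype=float)
        order = np.argsort(p)
        q = np.full_like(p, np.nan)
        m = np.sum(~np.isnan(p))
        ranked = p[order]
        qv = ranked * m / (np.arange(len(ranked)) + 1)
        qv = np.minimum.accumulate(qv[::-1])[::-1]
        q[order] = np.minimum(qv, 1.0)
        out["q_bh"] = q
    return out
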