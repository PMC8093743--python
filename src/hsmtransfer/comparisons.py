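"""Statistical comparison layer over the evaluation-record table.

All operations consume tidy record tables (one row per model x validation
mode), never rasters. The workflow: a Shapiro-Wilk gate on linear-model
residuals chooses parametric vs nonparametric testing; group comparisons use
Kruskal-Wallis with BH-adjusted pairwise rank-sum follow-ups (>= 3 classes)
or Mann-Whitney U with a Hodges-Lehmann shift estimate (2 classes); and the
novelty-transferability association is a Pearson correlation t test on
rank-based inverse-normal transformed metric and novelty values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult", "normality_gate", "compare_groups", "rint",
    "hodges_lehmann", "novelty_performance_correlation",
]


@dataclass
class ComparisonResult:
    test: str
    factor: str
    groups: tuple
    statistic: float
    p: float
    p_adjusted: Optional[float] = None
    estimated_difference: Optional[float] = None   # Hodges-Lehmann shift
    adjustment: Optional[str] = None


def normality_gate(metric: np.ndarray, factors: pd.DataFrame,
                   alpha: float = 0.05) -> str:
    """Choose 'parametric' or 'nonparametric' from linear-model residuals.

    Fits metric ~ factor dummies by least squares and applies the
    Shapiro-Wilk test to the residuals; p < alpha routes to nonparametric.
    """
    y = np.asarray(metric, dtype=float)
    if y.size < 8:
        raise ValueError("need >= 8 observations for the gate")
    if np.std(y) == 0:
        raise ValueError("constant metric: gate undefined")
    X = pd.get_dummies(factors.astype(str), drop_first=True, dtype=float)
    X.insert(0, "_const", 1.0)
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("degenerate factor design")
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    # Shapiro-Wilk is defined for n <= 5000; subsample deterministically
    if resid.size > 5000:
        resid = resid[:: resid.size // 5000 + 1]
    p = stats.shapiro(resid).pvalue
    return "nonparametric" if p < alpha else "parametric"


def hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise differences x_i - y_j (two-sample HL shift)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.median(np.subtract.outer(x, y)))


def compare_groups(records: pd.DataFrame, metric: str, factor: str,
                   one_tailed: Optional[str] = None,
                   alpha: float = 0.05) -> list[ComparisonResult]:
    """Nonparametric comparison of a metric across the levels of a factor.

    Two levels: Mann-Whitney U (one-tailed if ``one_tailed`` gives the level
    expected to be greater) with a Hodges-Lehmann shift estimate. Three or
    more: Kruskal-Wallis, followed by all pairwise rank-sum tests with
    Benjamini-Hochberg adjustment within the family.
    """
    groups = [(lvl, sub[metric].dropna().to_numpy())
              for lvl, sub in records.groupby(factor, sort=True)]
    groups = [(l, v) for l, v in groups if v.size > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if any(v.size < 3 for _, v in groups):
        raise ValueError("each group needs >= 3 observations")
    if len(groups) == 2:
        (la, a), (lb, b) = groups
        if one_tailed is None:
            alt = "two-sided"
        elif one_tailed == la:
            alt = "greater"
        elif one_tailed == lb:
            alt = "less"
        else:
            raise ValueError(f"one_tailed={one_tailed!r} is not a level")
        res = stats.mannwhitneyu(a, b, alternative=alt)
        return [ComparisonResult("mann-whitney-u", factor, (la, lb),
                                 float(res.statistic), float(res.pvalue),
                                 estimated_difference=hodges_lehmann(a, b))]
    kw = stats.kruskal(*[v for _, v in groups])
    out = [ComparisonResult("kruskal-wallis", factor,
                            tuple(l for l, _ in groups),
                            float(kw.statistic), float(kw.pvalue))]
    pairs, raw_p, stats_u, hls = [], [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            (la, a), (lb, b) = groups[i], groups[j]
            r = stats.mannwhitneyu(a, b, alternative="two-sided")
            pairs.append((la, lb))
            raw_p.append(float(r.pvalue))
            stats_u.append(float(r.statistic))
            hls.append(hodges_lehmann(a, b))
    adj = multipletests(raw_p, method="fdr_bh")[1]
    for (la, lb), u, p, pa, hl in zip(pairs, stats_u, raw_p, adj, hls):
        out.append(ComparisonResult("pairwise-rank-sum", factor, (la, lb),
                                    u, p, float(pa), hl, adjustment="BH"))
    return out


def rint(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    x_i -> Phi^{-1}((rank_i - 3/8) / (n + 1/4)); ties get average ranks.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct values for RINT")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def novelty_performance_correlation(records: pd.DataFrame,
                                    metrics: tuple[str, ...] = ("auc", "B"),
                                    novelty_col: str = "pct_nonanalog",
                                    by_mode: bool = False) -> pd.DataFrame:
    """Correlation t tests between transferability metrics and novelty.

    Pearson r is computed on RINT-transformed metric and RINT-transformed
    percent-nonanalog values, pooled across validation modes (optionally
    also per mode). Returns rows of (metric, mode, r, t, df, p).
    """
    rows = []
    subsets = [("pooled", records)]
    if by_mode:
        subsets += [(m, sub) for m, sub in records.groupby("mode")]
    for mode, sub in subsets:
        for metric in metrics:
            ok = sub[[metric, novelty_col]].dropna()
            if len(ok) < 10:
                continue
            try:
                xm = rint(ok[metric].to_numpy())
                xn = rint(ok[novelty_col].to_numpy())
            except ValueError:
                continue
            if np.std(xm) == 0 or np.std(xn) == 0:
                raise ValueError("zero variance after transform")
            r = float(np.corrcoef(xm, xn)[0, 1])
            df = len(ok) - 2
            t = r * np.sqrt(df / (1.0 - r ** 2))
            p = 2 * stats.t.sf(abs(t), df)
            rows.append(dict(metric=metric, mode=mode, r=r, t=float(t),
                             df=df, p=float(p), n=len(ok)))
    return pd.DataFrame(rows)
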