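"""Nonparametric statistical battery for method comparison.

The distance measurements produced by surface superimposition are bounded
below by zero and typically right-skewed, so the comparison of methods
runs on ranks: normality screening (Shapiro–Wilk plus Lilliefors-corrected
Kolmogorov–Smirnov), Kruskal–Wallis omnibus test, and Dunn's pairwise
post hoc z-tests with Bonferroni correction, all two-sided at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "TestResult",
    "PairwiseComparison",
    "kruskal_wallis",
    "dunn_bonferroni",
    "normality_screen",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class GroupSamples:
    """Named groups of real-valued observations (MADs or differences, mm)."""

    groups: dict  # name -> 1-D array

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        clean = {}
        for name, values in self.groups.items():
            arr = np.asarray(values, dtype=float).reshape(-1)
            if arr.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if not np.isfinite(arr).all():
                raise ValueError(f"group {name!r} contains non-finite values")
            clean[name] = arr
        self.groups = clean

    def names(self):
        return list(self.groups)

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))

    @property
    def total_n(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float  # Dunn z
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | None
    pvalue: float
    alpha: float = ALPHA
    pairwise: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": f"{c.group_a} vs {c.group_b}",
                    "statistic": c.statistic,
                    "p": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in self.pairwise
            ]
        )


def kruskal_wallis(samples: GroupSamples) -> TestResult:
    """Kruskal–Wallis H (mid-ranks, tie-corrected) with the χ² approximation.

    The degenerate all-identical case is reported as H = 0, p = 1.
    """
    values = list(samples.groups.values())
    if samples.total_n < 3:
        raise ValueError("Kruskal-Wallis needs a total sample size of at least 3")
    pooled = samples.pooled()
    df = len(values) - 1
    if np.all(pooled == pooled[0]):
        return TestResult(name="kruskal_wallis", statistic=0.0, df=df, pvalue=1.0)
    h, p = sps.kruskal(*values)
    return TestResult(name="kruskal_wallis", statistic=float(h), df=df, pvalue=float(p))


def dunn_bonferroni(samples: GroupSamples) -> TestResult:
    """Dunn's pairwise post hoc z-tests on pooled mid-ranks.

    Two-sided p-values are Bonferroni-multiplied by the number of pairs
    k(k−1)/2 and clamped at 1. The omnibus Kruskal–Wallis result is
    attached as the parent statistic.
    """
    omnibus = kruskal_wallis(samples)
    names = samples.names()
    pooled = samples.pooled()
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    start = 0
    for name in names:
        size = len(samples.groups[name])
        mean_ranks[name] = float(np.mean(ranks[start : start + size]))
        sizes[name] = size
        start += size

    n_pairs = len(names) * (len(names) - 1) // 2
    comparisons = []
    for a, b in combinations(names, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        comparisons.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                statistic=float(z),
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < ALPHA,
            )
        )
    return TestResult(
        name="dunn_bonferroni",
        statistic=omnibus.statistic,
        df=omnibus.df,
        pvalue=omnibus.pvalue,
        pairwise=comparisons,
    )


def normality_screen(sample) -> dict:
    """Shapiro–Wilk plus Lilliefors-corrected KS normality screen.

    Returns both test results and the branch decision: the nonparametric
    branch is taken when either p < α. A constant sample is non-normal by
    convention (p reported as 0).
    """
    arr = np.asarray(sample, dtype=float).reshape(-1)
    if arr.size < 3:
        raise ValueError("normality screen needs n >= 3")
    if np.all(arr == arr[0]):
        ks = TestResult(name="kolmogorov_smirnov_lilliefors", statistic=np.inf, df=None, pvalue=0.0)
        sw = TestResult(name="shapiro_wilk", statistic=0.0, df=None, pvalue=0.0)
        return {"kolmogorov_smirnov": ks, "shapiro_wilk": sw, "nonparametric": True}
    from statsmodels.stats.diagnostic import lilliefors

    ks_stat, ks_p = lilliefors(arr, dist="norm")
    sw_stat, sw_p = sps.shapiro(arr)
    ks = TestResult(
        name="kolmogorov_smirnov_lilliefors",
        statistic=float(ks_stat),
        df=None,
        pvalue=float(ks_p),
    )
    sw = TestResult(name="shapiro_wilk", statistic=float(sw_stat), df=None, pvalue=float(sw_p))
    return {
        "kolmogorov_smirnov": ks,
        "shapiro_wilk": sw,
        "nonparametric": bool(ks.pvalue < ALPHA or sw.pvalue < ALPHA),
    }
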