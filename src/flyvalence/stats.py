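"""Statistical procedures for grouped behavioral outcomes.

Implements the tests applied to the pipeline's outputs: the chi-square test
of equal proportions for exit-direction counts, the Dunn-Šidák correction
for families of comparisons, the Kruskal-Wallis omnibus test with Dunn's
rank-based post-test against a designated control group, and rank/linear
correlation for index-vs-index scatter (both Spearman's rho and Pearson's r
are always reported, together with the R² of the linear fit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EqualProportionsResult",
    "KruskalDunnResult",
    "CorrelationResult",
    "equal_proportions_test",
    "dunn_sidak",
    "kruskal_wallis_dunn",
    "rank_correlation",
]


@dataclass(frozen=True)
class EqualProportionsResult:
    statistic: float
    df: int
    pvalue: float


def equal_proportions_test(
    successes: Sequence[int],
    totals: Sequence[int],
    correction: Optional[bool] = None,
) -> EqualProportionsResult:
    """Chi-square test of homogeneity of k proportions.

    ``correction`` toggles the Yates continuity correction; the default
    (None) applies it only for two groups, the common convention. Any group
    with a zero total is an error.
    """
    s = np.asarray(successes, dtype=np.int64)
    t = np.asarray(totals, dtype=np.int64)
    if s.shape != t.shape or s.ndim != 1 or len(s) < 2:
        raise ValueError("need matching success/total vectors for >= 2 groups")
    if np.any(t <= 0):
        raise ValueError("every group needs a positive total")
    if np.any((s < 0) | (s > t)):
        raise ValueError("successes must satisfy 0 <= successes <= totals")
    if correction is None:
        correction = len(s) == 2
    table = np.vstack([s, t - s])
    # a margin of zeros (all successes or all failures) means identical
    # proportions; chi2_contingency cannot form expectations there
    if table[0].sum() == 0 or table[1].sum() == 0:
        return EqualProportionsResult(0.0, len(s) - 1, 1.0)
    chi2, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return EqualProportionsResult(float(chi2), int(df), float(p))


def dunn_sidak(p, m: int):
    """Šidák-adjust a p-value for a family of ``m`` comparisons:
    p_adj = 1 - (1 - p)^m, clipped to 1."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)) or np.any(np.isnan(p_arr)):
        raise ValueError("p must lie in [0, 1]")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError("m must be an integer >= 1")
    with np.errstate(divide="ignore"):  # p = 1 -> log 0 -> adj clips to 1
        adj = np.minimum(-np.expm1(m * np.log1p(-p_arr)), 1.0)
    return float(adj) if np.isscalar(p) or p_arr.ndim == 0 else adj


@dataclass(frozen=True)
class KruskalDunnResult:
    statistic: float
    pvalue: float
    dunn_z: dict
    dunn_p_raw: dict
    dunn_p_adjusted: dict
    control: int


def kruskal_wallis_dunn(
    samples: Sequence[Sequence[float]],
    control: int = 0,
    adjust: str = "sidak",
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test plus Dunn's post-test vs a control group.

    Dunn's z uses pooled mid-ranks with the tie correction; two-sided
    p-values are adjusted over the family of (k - 1) control comparisons
    with the Šidák correction by default (``adjust`` may also be
    "bonferroni" or "none"). When every pooled value is identical the
    omnibus statistic is 0 and all p-values are 1 (documented degenerate
    path).
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if not (0 <= control < len(groups)):
        raise ValueError("control index out of range")
    pooled = np.concatenate(groups)
    k = len(groups)
    comps = [i for i in range(k) if i != control]
    if np.all(pooled == pooled[0]):
        ones = {i: 1.0 for i in comps}
        zeros = {i: 0.0 for i in comps}
        return KruskalDunnResult(0.0, 1.0, zeros, ones, dict(ones), control)

    h, p = sps.kruskal(*groups)

    ranks = sps.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i]:offsets[i + 1]])) for i in range(k)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var0 = n * (n + 1) / 12.0 - tie_term

    z, p_raw = {}, {}
    for i in comps:
        se = np.sqrt(var0 * (1.0 / sizes[i] + 1.0 / sizes[control]))
        zi = (mean_ranks[i] - mean_ranks[control]) / se
        z[i] = float(zi)
        p_raw[i] = float(2.0 * sps.norm.sf(abs(zi)))
    m = len(comps)
    if adjust == "sidak":
        p_adj = {i: dunn_sidak(pi, m) for i, pi in p_raw.items()}
    elif adjust == "bonferroni":
        p_adj = {i: min(1.0, pi * m) for i, pi in p_raw.items()}
    elif adjust == "none":
        p_adj = dict(p_raw)
    else:
        raise ValueError("adjust must be 'sidak', 'bonferroni' or 'none'")
    return KruskalDunnResult(float(h), float(p), z, p_raw, p_adj, control)


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    r_squared: float
    defined: bool


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho and Pearson's r (with the linear-fit R²) for paired data.

    Zero variance in either variable leaves the correlations undefined
    (NaN, ``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return CorrelationResult(nan, nan, nan, nan, nan, False)
    rho, rho_p = sps.spearmanr(x, y)
    r, r_p = sps.pearsonr(x, y)
    return CorrelationResult(
        float(rho), float(rho_p), float(r), float(r_p), float(r) ** 2, True
    )
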