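"""Group statistics for pressure-dependent lumen measurements.

The measurement battery applied to grouped (per-pressure) area/height data:
one-way ANOVA, Tukey pairwise comparisons via the studentized-range
distribution, polynomial regression with r^2 and an overall F-test, and
boxplot summaries with 1%/99% whiskers.  F and q statistics are computed
from their definitional sums of squares; tail probabilities come from
scipy's F and studentized-range distributions (the latter evaluated by
numerical integration, not table lookup).

Significance conventions: p < 0.01 for ANOVA and r^2, p < 0.05 for Tukey
pairwise comparisons (both overridable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

ANOVA_ALPHA = 0.01
TUKEY_ALPHA = 0.05


@dataclass
class BoxplotSummary:
    median: float
    mean: float
    q1: float
    q3: float
    p1: float
    p99: float
    n: int


@dataclass
class PairwiseComparison:
    group_a: float
    group_b: float
    mean_diff: float
    q: float
    p: float
    significant: bool


def _validated_groups(groups: Mapping) -> dict:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    return out


def anova_oneway(groups: Mapping) -> tuple[float, float]:
    """Classical one-way ANOVA: (F, p).

    ``groups`` maps a group key (e.g. pressure in mmHg) to its measurement
    list.  Zero within-group variance with unequal means yields
    ``(inf, 0.0)`` with a warning.
    """
    gs = _validated_groups(groups)
    values = list(gs.values())
    n_total = sum(v.size for v in values)
    k = len(values)
    grand = np.concatenate(values).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_pairwise(groups: Mapping,
                   alpha: float = TUKEY_ALPHA) -> list[PairwiseComparison]:
    """All pairwise Tukey(-Kramer) comparisons.

    q = |mean_i - mean_j| / sqrt(s^2/2 * (1/n_i + 1/n_j)) with s^2 the
    pooled within-group variance; p from the studentized-range distribution
    with (k, N - k) parameters.
    """
    gs = _validated_groups(groups)
    k = len(gs)
    n_total = sum(v.size for v in gs.values())
    df_w = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in gs.values())
    if ss_within == 0:
        warnings.warn("zero within-group variance; q statistics are degenerate")
    s2 = ss_within / df_w
    out = []
    for a, b in combinations(gs, 2):
        va, vb = gs[a], gs[b]
        diff = va.mean() - vb.mean()
        if s2 == 0:
            q = 0.0 if diff == 0 else float("inf")
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(s2 / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        out.append(PairwiseComparison(group_a=a, group_b=b,
                                      mean_diff=float(diff), q=float(q),
                                      p=p, significant=p < alpha))
    return out


def polyfit_r2(x: Sequence[float], y: Sequence[float],
               degree: int = 2) -> tuple[np.ndarray, float, float]:
    """Polynomial least squares with r^2 and overall-regression F-test p.

    Returns ``(coefficients highest-power-first, r2, p)``.  Constant y is
    flagged and reported as r^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= degree + 1:
        raise ValueError("need n > degree + 1 points")
    coeffs = np.polyfit(x, y, degree)
    pred = np.polyval(coeffs, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        warnings.warn("constant response: r^2 defined as 0")
        return coeffs, 0.0, 1.0
    ss_res = float(((y - pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    df_reg, df_res = degree, n - degree - 1
    if ss_res == 0:
        return coeffs, r2, 0.0
    f = ((ss_tot - ss_res) / df_reg) / (ss_res / df_res)
    p = float(sps.f.sf(f, df_reg, df_res))
    return coeffs, r2, p


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median, mean, quartiles and 1%/99% whiskers of one sample.

    Quantiles use linear interpolation of order statistics (numpy's
    default convention).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    p1, q1, med, q3, p99 = np.quantile(v, [0.01, 0.25, 0.5, 0.75, 0.99])
    return BoxplotSummary(median=float(med), mean=float(v.mean()),
                          q1=float(q1), q3=float(q3), p1=float(p1),
                          p99=float(p99), n=int(v.size))
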