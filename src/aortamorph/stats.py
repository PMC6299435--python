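"""Between-group statistics: two-sample Kolmogorov–Smirnov test, F-test
of dispersion, and significance / trend flagging.

These are the comparisons applied to per-animal mean values (typically
n = 5 stacks per group): the KS test because the data are not Gaussian,
and a variance-ratio F-test to compare dispersion rather than location
for heterogeneous groups.  No multiple-testing correction is applied;
the comparison table records how many comparisons were made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy import special, stats as sp_stats

__all__ = [
    "ks_two_sample",
    "ks_statistic",
    "f_test_dispersion",
    "flag_significance",
    "GroupComparison",
    "compare_groups",
]

_EXACT_MAX_N = 10  # exact permutation enumeration for n, m <= 10


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """D = sup |F̂x − F̂y| over the pooled support."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_exact_pvalue(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Exhaustive permutation tail: the fraction of all C(n+m, n) splits
    of the pooled sample whose D is >= the observed one."""
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = range(len(pooled))
    count = 0
    total = 0
    for comb in _combinations(idx, n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        d = ks_statistic(pooled[sel], pooled[~sel])
        count += d >= d_obs - 1e-12
        total += 1
    return count / total


def _ks_asymptotic_pvalue(n: int, m: int, d: float) -> float:
    en = math.sqrt(n * m / (n + m))
    # standard finite-sample correction to the Kolmogorov limit law
    return float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    Returns ``(D, p)``.  For small samples (both n, m <= 10) p is the
    exact permutation tail probability; otherwise the asymptotic
    Kolmogorov formula is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = ks_statistic(x, y)
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        p = _ks_exact_pvalue(x, y, d)
    else:
        p = _ks_asymptotic_pvalue(len(x), len(y), d)
    return d, min(1.0, p)


def f_test_dispersion(x, y) -> tuple[float, float, tuple[int, int]]:
    """Two-sided variance-ratio F-test of dispersion.

    F = larger sample variance / smaller sample variance; the one-sided
    tail is doubled and capped at 1.  Returns ``(F, p, (dfn, dfd))``.
    Zero variance in both samples is undefined (ValueError); zero in one
    yields F = inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both samples have zero variance; F undefined")
    if vx >= vy:
        num, den, dfn, dfd = vx, vy, len(x) - 1, len(y) - 1
    else:
        num, den, dfn, dfd = vy, vx, len(y) - 1, len(x) - 1
    if den == 0.0:
        return float("inf"), 0.0, (dfn, dfd)
    f = num / den
    p = min(1.0, 2.0 * float(sp_stats.f.sf(f, dfn, dfd)))
    return f, p, (dfn, dfd)


def flag_significance(
    p: float,
    levels: tuple[float, float, float] = (0.05, 0.01, 0.001),
    trend_band: tuple[float, float] = (0.05, 0.08),
) -> str:
    """Flag a p value: *** / ** / * at the significance levels (boundary
    inclusive), # inside the trend band, else 'ns'."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value out of range: {p}")
    l1, l2, l3 = sorted(levels, reverse=True)
    if p <= l3:
        return "***"
    if p <= l2:
        return "**"
    if p <= l1:
        return "*"
    lo, hi = trend_band
    if lo < p <= hi:
        return "#"
    return "ns"


@dataclass
class GroupComparison:
    """One pairwise comparison of per-sample values between two groups."""

    group_a: str
    group_b: str
    parameter: str
    n_a: int
    n_b: int
    ks_d: float
    ks_p: float
    ks_flag: str
    f_stat: float
    f_p: float
    f_flag: str


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    levels: tuple[float, float, float] = (0.05, 0.01, 0.001),
    trend_band: tuple[float, float] = (0.05, 0.08),
) -> pd.DataFrame:
    """All pairwise KS + F comparisons of ``value_col`` between groups.

    One value per sample (animal/stack) is expected per row.  Returns a
    tidy table with a ``n_comparisons`` column recording the number of
    tests performed (no multiple-testing correction is applied).
    """
    groups = list(dict.fromkeys(values[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    pairs = list(_combinations(groups, 2))
    for ga, gb in pairs:
        xa = values.loc[values[group_col] == ga, value_col].to_numpy(dtype=float)
        xb = values.loc[values[group_col] == gb, value_col].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group size < 2 for {ga!r} vs {gb!r}")
        d, pk = ks_two_sample(xa, xb)
        try:
            f, pf, _ = f_test_dispersion(xa, xb)
        except ValueError:
            f, pf = float("nan"), float("nan")
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "parameter": value_col,
                "n_a": len(xa),
                "n_b": len(xb),
                "ks_d": d,
                "ks_p": pk,
                "ks_flag": flag_significance(pk, levels, trend_band),
                "f_stat": f,
                "f_p": pf,
                "f_flag": (
                    flag_significance(pf, levels, trend_band) if np.isfinite(pf) else "na"
                ),
                "n_comparisons": 2 * len(pairs),
            }
        )
    return pd.DataFrame(rows)
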