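"""Rank and contingency tests used across the occupancy and DEG modules.

The exact Mann-Whitney mode enumerates every assignment of the pooled
observations to the two groups (midranks for ties), so identical samples
give P = 1 exactly even with ties; the asymptotic mode delegates to scipy's
normal approximation with tie and continuity corrections. Fisher's exact
test delegates to scipy (two-sided by summation of hypergeometric
probabilities no larger than the observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["StatTestResult", "mann_whitney", "fisher_exact_2x2"]


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    medians: tuple[float, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #(x > y) pairs + 0.5 per tied pair."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # U_x = (rank sum of x) - n1(n1+1)/2 with midranks, so each labeling
    # costs one n1-term sum instead of an outer comparison.
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled).tolist()
    offset = n1 * (n1 + 1) / 2.0
    u_obs = _u_statistic(x, y)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    for chosen in combinations(ranks, n1):
        u = sum(chosen) - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / comb(n, n1)


def mann_whitney(x, y, mode: str = "auto") -> StatTestResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses exact enumeration when n1 + n2 <= 20 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections. ``exact`` forces enumeration (valid with ties; the null
    distribution of U is still symmetric under label exchange).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "normal_approx"
    medians = (float(np.median(x)), float(np.median(y)))
    if mode == "exact":
        u, p = _exact_p(x, y)
        return StatTestResult(u, min(1.0, p), "mann_whitney_exact",
                              len(x), len(y), medians)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return StatTestResult(float(res.statistic), float(res.pvalue),
                          "mann_whitney_normal_approx", len(x), len(y), medians)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> StatTestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return StatTestResult(float(odds) if np.isfinite(odds) else float("inf"),
                          float(p), "fisher_exact", a + b, c + d)
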