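"""Self-contained Pearson correlation and two-sided Mann-Whitney U test.

These are the only two statistics the pipeline reports. Both are authored
here rather than delegated, so their exact conventions (tie handling,
continuity correction, exact-mode enumeration) are fixed and documented;
only the t / normal distribution functions come from scipy.special.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    n2: Optional[int] = None
    flag: Optional[str] = None


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation with two-sided p from the t distribution.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    Raises on constant input (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("pearson: x and y must be 1-d of equal length")
    n = x.size
    if n < 3:
        raise StatsError(f"pearson: need n >= 3, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise StatsError("pearson: constant input vector, correlation undefined")
    r = float(dx @ dy) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        # two-sided tail of t with n-2 df; stdtr is the CDF
        p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return TestResult(statistic=r, p_value=min(1.0, p), n=n, method="pearson-t")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average of 1-based ranks i+1..j
        i = j
    return ranks


def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum()) - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``method``: 'exact' enumerates all group assignments of the pooled
    values (ties handled naturally); 'normal' uses the tie-corrected
    normal approximation with a 0.5 continuity correction; 'auto' picks
    exact when n1 + n2 <= 12. The reported statistic is U for sample ``a``.
    """
    if alternative != "two-sided":
        raise StatsError("only the two-sided alternative is implemented")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise StatsError("mann_whitney_u: both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u = _u_statistic(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if n1 + n2 <= 12 else "normal"

    if method == "exact":
        dev = abs(u - mu)
        total = 0
        hits = 0
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            total += 1
            u_c = float(ranks[list(combo)].sum()) - n1 * (n1 + 1) / 2.0
            if abs(u_c - mu) >= dev - 1e-9:
                hits += 1
        return TestResult(
            statistic=u, p_value=hits / total, n=n1, n2=n2, method="mwu-exact"
        )

    if method != "normal":
        raise StatsError(f"unknown method {method!r}")

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(
            statistic=u, p_value=1.0, n=n1, n2=n2, method="mwu-normal",
            flag="all values tied",
        )
    z = u - mu
    if continuity:
        z -= 0.5 * math.copysign(1.0, z) if z != 0 else 0.0
    z /= math.sqrt(sigma2)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return TestResult(
        statistic=u, p_value=min(1.0, p), n=n1, n2=n2, method="mwu-normal"
    )
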