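"""Exact binomial tail probabilities, stable for very large n.

The burden tests compare observed mutation counts against null proportions
with trial counts ranging from tens (LoF among coding SNVs) to billions
(callable bases).  Tail sums are therefore computed from a log-space anchor
point-probability with a multiplicative recurrence, never by enumerating
the support: the number of terms summed is bounded by the width of the
distribution around the anchor, so n = 1e10 costs no more than n = 100.

The two-sided p-value follows the minimum-likelihood construction used by
R's ``binom.test``: the sum of P(X = j) over all j whose point probability
does not exceed that of the observed count (within a relative fuzz of
1e-7, as in R).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

_REL_ERR = 1 + 1e-7  # R binom.test fuzz for the minimum-likelihood rule
_SUM_TOL = 1e-18  # stop a tail sum once increments are negligible

_HALF_LOG_2PI = 0.5 * math.log(2 * math.pi)


def _stirlerr(n: int) -> float:
    """Stirling-series error term log(n!) - [Stirling approximation].

    Direct log-gamma is fully accurate for small n; the asymptotic series
    takes over where log-gamma magnitudes would start eating significant
    digits in the pmf's cancellation.
    """
    if n < 16:
        return math.lgamma(n + 1) - (n + 0.5) * math.log(n) + n - _HALF_LOG_2PI
    nn = float(n) * n
    return (
        1.0 / (12.0 * n)
        - 1.0 / (360.0 * n * nn)
        + 1.0 / (1260.0 * n * nn * nn)
        - 1.0 / (1680.0 * n * nn * nn * nn)
    )


def _bd0(x: float, m: float) -> float:
    """Binomial deviance x*log(x/m) + m - x, cancellation-safe near x = m."""
    if x == 0.0:
        return m
    if abs(x - m) < 0.1 * (x + m):
        v = (x - m) / (x + m)
        s = (x - m) * v
        ej = 2.0 * x * v
        v2 = v * v
        j = 1
        while True:
            ej *= v2
            s1 = s + ej / (2 * j + 1)
            if s1 == s:
                return s1
            s = s1
            j += 1
    return x * math.log(x / m) + m - x


def log_binom_pmf(k: int, n: int, p0: float) -> float:
    """log P(X = k) for X ~ Binomial(n, p0), saddle-point evaluation.

    Full double precision even for n in the billions, where a log-gamma
    difference would lose ~6 digits to cancellation.
    """
    if k < 0 or k > n:
        return -math.inf
    if p0 == 0.0:
        return 0.0 if k == 0 else -math.inf
    if p0 == 1.0:
        return 0.0 if k == n else -math.inf
    if k == 0:
        return n * math.log1p(-p0)
    if k == n:
        return n * math.log(p0)
    lc = (
        _stirlerr(n)
        - _stirlerr(k)
        - _stirlerr(n - k)
        - _bd0(k, n * p0)
        - _bd0(n - k, n * (1.0 - p0))
    )
    return lc + 0.5 * math.log(n / (2 * math.pi * k * (n - k)))


def _sum_upper(k: int, n: int, p0: float) -> float:
    """P(X >= k), summing upward from k while terms decay to nothing."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    log_anchor = log_binom_pmf(k, n, p0)
    if log_anchor == -math.inf:
        return 0.0
    odds = p0 / (1.0 - p0)
    total = term = 1.0
    j = k
    while j < n:
        term *= (n - j) / (j + 1) * odds
        total += term
        j += 1
        if term <= _SUM_TOL * total and j > n * p0:
            break
    return min(1.0, math.exp(log_anchor) * total)


def _sum_lower(k: int, n: int, p0: float) -> float:
    """P(X <= k), summing downward from k."""
    if k >= n:
        return 1.0
    if k < 0:
        return 0.0
    log_anchor = log_binom_pmf(k, n, p0)
    if log_anchor == -math.inf:
        return 0.0
    inv_odds = (1.0 - p0) / p0
    total = term = 1.0
    j = k
    while j > 0:
        term *= j / (n - j + 1) * inv_odds
        total += term
        j -= 1
        if term <= _SUM_TOL * total and j < n * p0:
            break
    return min(1.0, math.exp(log_anchor) * total)


def binom_sf(k: int, n: int, p0: float) -> float:
    """P(X >= k), computed on whichever tail is numerically smaller."""
    if k <= n * p0:
        return 1.0 - _sum_lower(k - 1, n, p0)
    return _sum_upper(k, n, p0)


def binom_cdf(k: int, n: int, p0: float) -> float:
    """P(X <= k)."""
    if k >= n * p0:
        return 1.0 - _sum_upper(k + 1, n, p0)
    return _sum_lower(k, n, p0)


def _search_pmf_below(n: int, p0: float, threshold: float, lo: int, hi: int, increasing: bool) -> int:
    """Boundary search on a monotone flank of the unimodal pmf.

    Returns the outermost index j in [lo, hi] (towards the tail) such that
    log-pmf(j) <= threshold for all indices beyond it; ``increasing`` says
    whether pmf grows with j on this flank (left flank) or shrinks (right).
    """
    # binary search for the first index (moving away from the mode) with
    # pmf <= threshold
    if increasing:
        # left flank: pmf increases with j; find largest j with pmf <= threshold
        if log_binom_pmf(lo, n, p0) > threshold:
            return lo - 1
        a, b = lo, hi  # invariant: pmf(a) <= threshold
        while a < b:
            mid = (a + b + 1) // 2
            if log_binom_pmf(mid, n, p0) <= threshold:
                a = mid
            else:
                b = mid - 1
        return a
    # right flank: pmf decreases with j; find smallest j with pmf <= threshold
    if log_binom_pmf(hi, n, p0) > threshold:
        return hi + 1
    a, b = lo, hi  # invariant: pmf(b) <= threshold
    while a < b:
        mid = (a + b) // 2
        if log_binom_pmf(mid, n, p0) <= threshold:
            b = mid
        else:
            a = mid + 1
    return b


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided minimum-likelihood p-value (R ``binom.test`` construction)."""
    mean = n * p0
    log_d = log_binom_pmf(k, n, p0) + math.log(_REL_ERR)
    mode = math.floor((n + 1) * p0)
    if k == mode or math.isclose(k, mean, rel_tol=1e-12):
        return 1.0
    if k < mean:
        left = _sum_lower(k, n, p0)
        j = _search_pmf_below(n, p0, log_d, mode, n, increasing=False)
        right = _sum_upper(j, n, p0) if j <= n else 0.0
        return min(1.0, left + right)
    right = _sum_upper(k, n, p0)
    j = _search_pmf_below(n, p0, log_d, 0, mode, increasing=True)
    left = _sum_lower(j, n, p0) if j >= 0 else 0.0
    return min(1.0, left + right)


@dataclass(frozen=True)
class BurdenResult:
    """Outcome of one exact binomial burden comparison."""

    k: int
    n: int
    p0: float
    alternative: str  # {greater, less, two_sided_minlik}
    p_value: float
    description: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("k outside [0, n]")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 outside [0, 1]")


def exact_binomial_test(
    k: int, n: int, p0: float, alternative: str = "greater", description: str = ""
) -> BurdenResult:
    """Exact binomial test of k successes in n trials against p0.

    ``alternative`` is one of ``greater`` (upper tail), ``less`` (lower
    tail) or ``two_sided_minlik`` (R-style two-sided).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if p0 in (0.0, 1.0):
        # degenerate nulls: the distribution is a point mass
        if alternative == "greater":
            p = 1.0 if (k == 0 or p0 == 1.0) else 0.0
        elif alternative == "less":
            p = 1.0 if (k == n or p0 == 0.0) else 0.0
        else:
            p = 1.0 if k == (n if p0 == 1.0 else 0) else 0.0
        return BurdenResult(k, n, p0, alternative, p, description)
    if alternative == "greater":
        p = binom_sf(k, n, p0)
    elif alternative == "less":
        p = binom_cdf(k, n, p0)
    elif alternative == "two_sided_minlik":
        p = binom_two_sided(k, n, p0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return BurdenResult(k, n, p0, alternative, p, description)
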