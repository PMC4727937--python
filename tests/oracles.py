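"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (enumeration, direct summation,
sort-and-slice) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import math

import numpy as np


def poisson_cdf_cutoff(lam: float, percentile: float, k_max: int = 100_000) -> int:
    """Smallest k with Poisson(lam) CDF >= percentile, by direct pmf summation."""
    total = 0.0
    log_pmf = -lam
    for k in range(k_max):
        if k > 0:
            log_pmf += math.log(lam) - math.log(k)
        total += math.exp(log_pmf)
        if total >= percentile:
            return k
    raise RuntimeError("cutoff not reached")


def quantile_linear(sorted_values, q: float) -> float:
    """Linear-interpolation quantile of pre-sorted values (type 7)."""
    x = list(sorted_values)
    n = len(x)
    if n == 1:
        return float(x[0])
    h = q * (n - 1)
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return float(x[lo] + (h - lo) * (x[hi] - x[lo]))


def brute_high_coverage_filter(rows, percentile: float):
    """Rows surviving the Poisson coverage cut; rows are (chrom,pos,a,b)."""
    covs = sorted(a + b for _, _, a, b in rows)
    n = len(covs)
    med = (covs[(n - 1) // 2] + covs[n // 2]) / 2.0
    cutoff = poisson_cdf_cutoff(med, percentile)
    return [r for r in rows if r[2] + r[3] <= cutoff]


def brute_quantile_trim(rows, tail: float):
    """Rows inside the closed central coverage-quantile interval."""
    if tail == 0.0:
        return list(rows)
    covs = sorted(a + b for _, _, a, b in rows)
    lo = quantile_linear(covs, tail)
    hi = quantile_linear(covs, 1.0 - tail)
    return [r for r in rows if lo <= r[2] + r[3] <= hi]


def brute_combine(tables):
    """Sum counts per (chrom, pos) over a list of row-lists."""
    acc: dict[tuple, list[int]] = {}
    for rows in tables:
        for chrom, pos, a, b in rows:
            cur = acc.setdefault((chrom, pos), [0, 0])
            cur[0] += a
            cur[1] += b
    return [
        (chrom, pos, a, b)
        for (chrom, pos), (a, b) in sorted(acc.items())
    ]


def brute_sliding_median(values, window: int):
    """O(n*w) centred sliding median with symmetric shrink at the edges."""
    v = list(values)
    n = len(v)
    half = (window - 1) // 2
    out = []
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out.append(float(np.median(v[i - h : i + h + 1])))
    return out


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def binom_sf_ge(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(binom_pmf(i, n, p) for i in range(k, n + 1))


def clopper_pearson_by_grid(k: int, n: int, confidence: float, step: float = 1e-4):
    """Exact binomial CI by scanning p over a grid and inverting the tails."""
    alpha = 1.0 - confidence
    grid = np.arange(0.0, 1.0 + step / 2, step)
    lower = 0.0
    if k > 0:
        ok = [p for p in grid if binom_sf_ge(k, n, p) >= alpha / 2.0]
        lower = min(ok) if ok else 1.0
    upper = 1.0
    if k < n:
        ok = [p for p in grid if 1.0 - binom_sf_ge(k + 1, n, p) >= alpha / 2.0]
        upper = max(ok) if ok else 0.0
    return lower, upper


def haldane_by_poisson_process(d_cm: float, n: int, rng) -> float:
    """Recombination fraction by simulating a Poisson crossover process."""
    crossovers = rng.poisson(d_cm / 100.0, size=n)
    return float((crossovers % 2 == 1).mean())
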