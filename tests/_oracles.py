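"""Independent brute-force oracles used to validate the implementation.

Each oracle reaches the same quantity as the production code by a
different computational route (direct convolution, exhaustive grid search,
exact rational enumeration), so agreement is evidence of correctness
rather than self-consistency.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, exp, factorial

import numpy as np


def convolution_ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbrueck pmf by compounding a Poisson number of clones.

    P(R = r) = sum_n Poisson(n; m) * q^{*n}(r) with q(k) = 1/(k(k+1)),
    convolved directly. Truncates the Poisson sum when the remaining mass
    is below 1e-16 relative to machine precision.
    """
    q = np.zeros(r_max + 1)
    ks = np.arange(1, r_max + 1, dtype=float)
    q[1:] = 1.0 / (ks * (ks + 1.0))

    # enough Poisson terms that the neglected tail is < 1e-14
    n_max = 5
    while True:
        tail = 1.0 - sum(exp(-m) * m**n / factorial(n) for n in range(n_max + 1))
        if tail < 1e-14 or n_max > 500:
            break
        n_max += 5

    pmf = np.zeros(r_max + 1)
    conv = np.zeros(r_max + 1)
    conv[0] = 1.0  # q^{*0} = point mass at 0
    pmf += exp(-m) * conv
    for n in range(1, n_max + 1):
        conv = np.convolve(conv, q)[: r_max + 1]
        pmf += exp(-m) * m**n / factorial(n) * conv
    return pmf


def grid_argmax_loglik(counts, grid: np.ndarray, loglik) -> float:
    """Exhaustive grid search for the maximising m of a log-likelihood."""
    values = np.array([loglik(counts, m) for m in grid])
    return float(grid[int(np.argmax(values))])


def bisect_median_equation(r_median: float, tol: float = 1e-12) -> float:
    """Solve r/m - ln(m) = 1.24 by plain interval bisection."""
    f = lambda m: (r_median / m if r_median > 0 else 0.0) - np.log(m) - 1.24
    lo, hi = 1e-12, 1.0
    while f(hi) > 0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:
            break
    return 0.5 * (lo + hi)


def median_ci_ranks_by_enumeration(n: int, level: float = 0.95):
    """Order-statistic ranks for the median CI by direct binomial summation.

    Exact rational arithmetic: k is the largest rank with
    P(X <= k-1) <= (1-level)/2 for X ~ Binomial(n, 1/2).
    """
    alpha2 = Fraction(1 - Fraction(str(level)), 2)
    best = None
    cum = Fraction(0)
    for j in range(n + 1):
        cum += Fraction(comb(n, j), 2**n)
        if cum <= alpha2:
            best = j + 1  # k with P(X <= k-1) = cum
    if best is None:
        return None
    achieved = 1 - 2 * sum(Fraction(comb(n, j), 2**n) for j in range(best))
    return best, n + 1 - best, float(achieved)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration.

    Sums P(table) over all tables at the observed margins whose probability
    does not exceed the observed one (with the conventional 1e-7 relative
    slack for floating-point ties, applied here in exact arithmetic).
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    threshold = Fraction(weights[a]) * (1 + Fraction(1, 10**7))
    kept = sum(w for w in weights.values() if w <= threshold)
    return float(Fraction(kept, total))


def mann_whitney_exact_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all label assignments.

    Feasible only for tiny samples; assumes tie-free pooled data.
    """
    from itertools import combinations

    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    u_obs = sum(sum(1 for yy in y if xx > yy) for xx in x)
    mean_u = n * m / 2
    count = 0
    total = 0
    for positions in combinations(range(n + m), n):
        xs = [pooled[i] for i in positions]
        ys = [pooled[i] for i in range(n + m) if i not in positions]
        u = sum(sum(1 for yy in ys if xx > yy) for xx in xs)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def spearman_exact_p_bruteforce(x, y) -> float:
    """Exact permutation p for |Spearman rho| via pure-python enumeration."""
    from itertools import permutations

    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)

    def rho(a, b):
        ca = a - np.mean(a)
        cb = b - np.mean(b)
        return float(np.dot(ca, cb) / np.sqrt(np.dot(ca, ca) * np.dot(cb, cb)))

    obs = abs(rho(rx, ry))
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(rho(rx, ry[list(perm)])) >= obs - 1e-12:
            hits += 1
    return hits / total
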