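"""The Luria-Delbrueck mutant-count distribution.

In a fluctuation assay, parallel cultures grow from a small inoculum to a
final population of ``Nt`` cells and are plated on selective medium. A
mutation arising early in the growth of a culture founds a clone that is
large by the time of plating ("jackpot"), so the number of mutant colonies
per culture is heavily over-dispersed relative to Poisson. Under the
classical Lea-Coulson formulation the number of mutation *events* per
culture is Poisson with mean ``m``, and each event founds a clone whose
final size ``C`` follows ``P(C = k) = 1/(k(k+1))`` for ``k >= 1``. The
resulting mutant-count pmf ``p_r`` obeys the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m)
    p_r = (m/r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

which this module tabulates, together with the log-likelihood used by the
maximum-likelihood estimator.

All quantities are computed in linear double precision; ``p_0 = exp(-m)``
only underflows near ``m ~ 745``, far beyond the ``m <= ~100`` range of a
practicable assay design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = ["LDParams", "PmfTable", "clone_size_pmf", "ld_pmf", "ld_loglik"]


@dataclass(frozen=True)
class LDParams:
    """Parameters of a tabulated Luria-Delbrueck distribution.

    Parameters
    ----------
    m : float
        Expected number of mutation events per culture (dimensionless, >= 0).
    r_max : int
        Largest mutant count for which the pmf is tabulated (>= 0).
    """

    m: float
    r_max: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.m) or self.m < 0:
            raise DomainError(f"m must be finite and >= 0, got {self.m!r}")
        if int(self.r_max) != self.r_max or self.r_max < 0:
            raise DomainError(f"r_max must be an integer >= 0, got {self.r_max!r}")

    def pmf(self) -> "PmfTable":
        return ld_pmf(self.m, self.r_max)


@dataclass(frozen=True)
class PmfTable:
    """Tabulated pmf ``P(R = r)`` for ``r = 0..r_max`` plus the tail mass.

    ``tail_mass`` is computed as the exact complement ``1 - sum(probabilities)``
    rather than by extending the recursion, so the table always sums to one.
    """

    m: float
    probabilities: np.ndarray
    tail_mass: float

    @property
    def r_max(self) -> int:
        return len(self.probabilities) - 1

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probabilities)

    def median(self) -> int:
        """Smallest r with CDF(r) >= 1/2 (population median of the counts)."""
        c = self.cdf()
        idx = np.nonzero(c >= 0.5)[0]
        if len(idx) == 0:
            raise DomainError("r_max too small to contain the median")
        return int(idx[0])


def clone_size_pmf(k):
    """Probability that a mutant clone has final size ``k``.

    The Lea-Coulson clone-size law ``P(C = k) = 1/(k(k+1))`` for integer
    ``k >= 1``; the sequence telescopes to 1 over ``k >= 1``. Accepts a
    scalar or array of integers.
    """
    arr = np.asarray(k)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.asarray(arr, dtype=float) == np.floor(arr)):
            raise DomainError("clone size k must be integer")
        arr = np.asarray(arr, dtype=np.int64)
    if np.any(arr < 1):
        raise DomainError("clone size k must be >= 1")
    out = 1.0 / (arr.astype(float) * (arr.astype(float) + 1.0))
    return float(out) if np.isscalar(k) or arr.ndim == 0 else out


def ld_pmf(m: float, r_max: int) -> PmfTable:
    """Tabulate the Luria-Delbrueck mutant-count pmf up to ``r_max``.

    Uses the Ma-Sandri-Sarkar recursion; for ``m = 0`` returns a point mass
    at ``r = 0``.
    """
    params = LDParams(m, r_max)  # validates
    r_max = int(params.r_max)
    p = np.zeros(r_max + 1)
    if m == 0:
        p[0] = 1.0
        return PmfTable(m=m, probabilities=p, tail_mass=0.0)
    p[0] = np.exp(-m)
    # c[j] = 1/(j+1); the r-th step needs weights 1/(r-i+1) for i = 0..r-1,
    # i.e. c reversed over j = 1..r.
    c = 1.0 / (np.arange(r_max + 1, dtype=float) + 1.0)
    for r in range(1, r_max + 1):
        p[r] = (m / r) * np.dot(p[:r], c[r:0:-1])
    tail = 1.0 - float(p.sum())
    return PmfTable(m=m, probabilities=p, tail_mass=max(tail, 0.0))


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValidationError("counts must be non-empty")
    flt = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(flt)) or np.any(flt != np.floor(flt)):
        raise ValidationError("counts must be non-negative integers")
    if np.any(flt < 0):
        raise ValidationError("counts must be non-negative integers")
    return flt.astype(np.int64)


def ld_loglik(counts, m: float, censor_at: int | None = None) -> float:
    """Log-likelihood ``sum_i log p_{r_i}(m)`` of a vector of mutant counts.

    The pmf is tabulated once up to the largest needed count. If
    ``censor_at`` is given, counts exceeding it contribute ``log P(R > censor_at)``
    (exact right-censoring via the tail mass) instead of a point probability,
    which bounds tabulation cost for jackpot cultures without biasing the
    likelihood.
    """
    arr = _validate_counts(counts)
    if not np.isfinite(m) or m < 0:
        raise DomainError(f"m must be finite and >= 0, got {m!r}")
    if m == 0:
        return 0.0 if np.all(arr == 0) else float("-inf")
    if censor_at is not None:
        censor_at = int(censor_at)
        censored = arr > censor_at
        observed = arr[~censored]
        r_tab = censor_at if censored.any() else (int(observed.max()) if observed.size else 0)
    else:
        censored = np.zeros(arr.shape, dtype=bool)
        observed = arr
        r_tab = int(arr.max())
    table = ld_pmf(m, r_tab)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(np.log(table.probabilities[observed]))) if observed.size else 0.0
        n_cens = int(censored.sum())
        if n_cens:
            ll += n_cens * float(np.log(table.tail_mass)) if table.tail_mass > 0 else float("-inf")
    return ll
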