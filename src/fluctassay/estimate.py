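"""Mutation-rate estimation from fluctuation-assay data.

Three estimators of ``m``, the expected number of mutation events per
culture, are provided behind a statsmodels-style model/results pair:

``median_lc``
    The Lea-Coulson median method: solve ``r_med/m - ln(m) = 1.24`` for
    ``m``, where ``r_med`` is the sample median mutant count. This is the
    standard workhorse of yeast fluctuation assays; its 95% interval is the
    distribution-free order-statistic interval for the median, mapped
    through the (monotone) defining equation.
``p0``
    The null-class method ``m = -ln(P0)`` with ``P0`` the fraction of
    cultures without mutants; interval by Clopper-Pearson on ``P0``.
    Applicable only when zero-count cultures exist (low rates).
``mle``
    Ma-Sandri-Sarkar maximum likelihood under the full Luria-Delbrueck
    pmf, with profile-likelihood intervals and exact right-censoring of
    jackpot counts above a cap. The statistically efficient cross-check.

Rates per cell are ``mu = m / Nt`` (per generation would divide by an
additional ``ln 2``; only relative rates matter downstream, for which the
constant cancels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import CultureSet
from .distribution import ld_loglik, ld_pmf
from .exceptions import (
    DomainError,
    MethodInapplicableError,
    NumericalError,
    ValidationError,
)

__all__ = [
    "LEA_COULSON_CONSTANT",
    "RateEstimate",
    "FluctuationModel",
    "lea_coulson_m",
    "median_ci",
    "rate_per_cell",
    "estimate_p0",
    "estimate_median_lc",
    "estimate_mle",
    "estimate_auto",
]

#: Constant of the Lea-Coulson median equation r/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24

#: Counts above this cap are right-censored in the MLE (exact tail mass).
DEFAULT_JACKPOT_CAP = 10_000


# ---------------------------------------------------------------------------
# results object


@dataclass
class RateEstimate:
    """Results of fitting one fluctuation experiment.

    Attributes
    ----------
    m_hat : float
        Estimated mutation events per culture.
    mu_hat : float
        Estimated rate per cell, ``m_hat / Nt``.
    ci_low, ci_high : float
        95% interval bounds on ``mu_hat`` (NaN when not computable).
    method : str
        One of ``median_lc``, ``p0``, ``mle``.
    achieved_confidence : float
        Actual (conservative) coverage of the order-statistic interval for
        ``median_lc``; NaN for the other methods.
    """

    m_hat: float
    mu_hat: float
    ci_low: float
    ci_high: float
    method: str
    n_cultures: int
    Nt: float
    strain_id: str = ""
    reporter: str = ""
    achieved_confidence: float = float("nan")
    level: float = 0.95
    loglik: float | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "reporter": self.reporter,
            "method": self.method,
            "n_cultures": self.n_cultures,
            "m_hat": self.m_hat,
            "mu_hat": self.mu_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "achieved_confidence": self.achieved_confidence,
        }

    def summary(self) -> str:
        lines = [
            "Fluctuation assay rate estimate",
            "===============================",
            f"strain / reporter : {self.strain_id or '-'} / {self.reporter or '-'}",
            f"method            : {self.method}",
            f"cultures          : {self.n_cultures}",
            f"final cells Nt    : {self.Nt:.4g}",
            f"m (events/culture): {self.m_hat:.4g}",
            f"mu (per cell)     : {self.mu_hat:.4g}",
            f"{self.level:.0%} CI on mu     : [{self.ci_low:.4g}, {self.ci_high:.4g}]",
        ]
        if np.isfinite(self.achieved_confidence):
            lines.append(f"achieved coverage : {self.achieved_confidence:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# building blocks


def rate_per_cell(m_hat: float, Nt: float) -> float:
    """Normalise events-per-culture to a per-cell rate ``mu = m / Nt``."""
    if not (np.isfinite(Nt) and Nt > 0):
        raise DomainError(f"Nt must be positive, got {Nt!r}")
    if m_hat < 0:
        raise DomainError("m_hat must be >= 0")
    return m_hat / Nt


def lea_coulson_m(r_median: float) -> float:
    """Solve the Lea-Coulson median equation ``r/m - ln m = 1.24`` for m.

    The left-hand side is strictly decreasing in ``m``, so the root is
    unique; it is bracketed and refined to relative tolerance 1e-12.
    Defined for any ``r_median >= 0`` (used for CI bound mapping); the point
    estimator itself additionally requires ``r_median >= 1``.
    """
    if not np.isfinite(r_median) or r_median < 0:
        raise DomainError(f"median count must be finite and >= 0, got {r_median!r}")

    def f(m: float) -> float:
        return (r_median / m if r_median > 0 else 0.0) - math.log(m) - LEA_COULSON_CONSTANT

    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e9:
            raise NumericalError("no bracketing root in (1e-9, 1e9)")
    return float(optimize.brentq(f, lo, hi, rtol=1e-12, maxiter=200))


def median_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free order-statistic confidence interval for the median.

    Returns ``(low, high, achieved_confidence)`` where low/high are the
    k-th and (n+1-k)-th order statistics and ``k`` is the largest rank with
    ``P(X < k) <= (1-level)/2`` for ``X ~ Binomial(n, 1/2)``. The achieved
    confidence ``1 - 2 P(X <= k-1)`` is conservative (>= ``level``).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 6:
        raise MethodInapplicableError(
            f"order-statistic interval needs n >= 6 at level {level}, got n = {n}"
        )
    alpha2 = (1.0 - level) / 2.0
    cdf = stats.binom.cdf(np.arange(n), n, 0.5)  # cdf[j] = P(X <= j)
    eligible = np.nonzero(cdf <= alpha2)[0]
    if eligible.size == 0:
        raise MethodInapplicableError(
            f"no nontrivial order-statistic interval at level {level} for n = {n}"
        )
    k = int(eligible[-1]) + 1  # rank, 1-indexed
    achieved = 1.0 - 2.0 * float(cdf[k - 1])
    return float(v[k - 1]), float(v[n - k]), achieved


def median_ci_ranks(n: int, level: float = 0.95) -> tuple[int, int]:
    """The (lower, upper) order-statistic ranks used by :func:`median_ci`."""
    low, high, _ = median_ci(np.arange(1, n + 1), level=level)
    return int(low), int(high)


# ---------------------------------------------------------------------------
# estimators


def _check_plating(cs: CultureSet) -> None:
    if cs.plated_fraction < 1.0:
        warnings.warn(
            f"{cs.strain_id}/{cs.reporter}: plated_fraction = {cs.plated_fraction} < 1; "
            "estimators assume fully plated (or pre-scaled) counts",
            UserWarning,
            stacklevel=3,
        )


def estimate_p0(cs: CultureSet, level: float = 0.95) -> RateEstimate:
    """Null-class estimator ``m = -ln(fraction of zero-count cultures)``."""
    _check_plating(cs)
    counts = cs.counts
    n = counts.size
    zeros = int(np.count_nonzero(counts == 0))
    if zeros == 0:
        raise MethodInapplicableError(
            f"{cs.strain_id}/{cs.reporter}: no zero-count cultures; "
            "rates too high for the p0 method (use median_lc or mle)"
        )
    p0_hat = zeros / n
    m_hat = -math.log(p0_hat)
    lo_p, hi_p = stats.binomtest(zeros, n).proportion_ci(
        confidence_level=level, method="exact"
    )
    m_high = -math.log(lo_p) if lo_p > 0 else float("inf")
    m_low = -math.log(min(hi_p, 1.0))
    return RateEstimate(
        m_hat=m_hat,
        mu_hat=rate_per_cell(m_hat, cs.Nt),
        ci_low=rate_per_cell(max(m_low, 0.0), cs.Nt),
        ci_high=m_high / cs.Nt,
        method="p0",
        n_cultures=n,
        Nt=cs.Nt,
        strain_id=cs.strain_id,
        reporter=cs.reporter,
        level=level,
    )


def estimate_median_lc(
    cs: CultureSet, level: float = 0.95, per_culture: bool = False
) -> RateEstimate:
    """Lea-Coulson median method.

    By default (``per_culture=False``) the *median count* is fed to the
    defining equation — the procedure of the classical protocol. With
    ``per_culture=True`` each culture's count is converted to a
    single-culture ``m`` first and the median of those is reported (an
    alternative reading of "median rate"; both orderings select the same
    order statistics, so they differ only through the nonlinear map).
    """
    _check_plating(cs)
    counts = cs.counts
    r_med = float(np.median(counts))
    if r_med < 1:
        raise MethodInapplicableError(
            f"{cs.strain_id}/{cs.reporter}: median count {r_med} < 1; the median "
            "method is undefined (use p0 or mle)"
        )
    if per_culture:
        per = np.array([lea_coulson_m(max(float(r), 0.0)) for r in counts])
        m_hat = float(np.median(per))
    else:
        m_hat = lea_coulson_m(r_med)
    ci_low = ci_high = float("nan")
    achieved = float("nan")
    if counts.size >= 6:
        try:
            r_lo, r_hi, achieved = median_ci(counts, level=level)
            m_lo, m_hi = lea_coulson_m(r_lo), lea_coulson_m(r_hi)
            ci_low, ci_high = rate_per_cell(m_lo, cs.Nt), rate_per_cell(m_hi, cs.Nt)
        except MethodInapplicableError:
            pass
    return RateEstimate(
        m_hat=m_hat,
        mu_hat=rate_per_cell(m_hat, cs.Nt),
        ci_low=ci_low,
        ci_high=ci_high,
        method="median_lc",
        n_cultures=counts.size,
        Nt=cs.Nt,
        strain_id=cs.strain_id,
        reporter=cs.reporter,
        achieved_confidence=achieved,
        level=level,
    )


def _mle_initial_guess(counts: np.ndarray) -> float:
    med = float(np.median(counts))
    if med >= 1:
        return lea_coulson_m(med)
    zeros = int(np.count_nonzero(counts == 0))
    if 0 < zeros < counts.size:
        return -math.log(zeros / counts.size)
    return max(float(counts.mean()) / 5.0, 0.1)


def estimate_mle(
    cs: CultureSet,
    level: float = 0.95,
    jackpot_cap: int = DEFAULT_JACKPOT_CAP,
) -> RateEstimate:
    """Ma-Sandri-Sarkar maximum-likelihood estimator with profile CI.

    The interval is the profile-likelihood set at a log-likelihood drop of
    ``chi2_1(level)/2`` (1.92 at 95%). Counts above ``jackpot_cap`` enter
    the likelihood as exactly right-censored via the tail mass, bounding
    pmf tabulation cost without bias.
    """
    _check_plating(cs)
    counts = cs.counts
    n = counts.size
    drop = stats.chi2.ppf(level, df=1) / 2.0

    if np.all(counts == 0):
        # likelihood exp(-n m), maximised at the m = 0 boundary
        m_high = drop / n
        return RateEstimate(
            m_hat=0.0,
            mu_hat=0.0,
            ci_low=0.0,
            ci_high=rate_per_cell(m_high, cs.Nt),
            method="mle",
            n_cultures=n,
            Nt=cs.Nt,
            strain_id=cs.strain_id,
            reporter=cs.reporter,
            level=level,
            loglik=0.0,
        )

    def ll(m: float) -> float:
        value = ld_loglik(counts, m, censor_at=jackpot_cap)
        # clamp underflow so the bounded optimiser sees finite values
        return value if np.isfinite(value) else -1e300

    # optimise over log(m): the likelihood is smooth and unimodal there, and
    # geometric probe spacing keeps the search off the underflow plateau at
    # very large m
    m0 = _mle_initial_guess(counts)
    lo, hi = math.log(max(m0 / 100.0, 1e-8)), math.log(m0 * 100.0)
    for _ in range(6):
        res = optimize.minimize_scalar(
            lambda t: -ll(math.exp(t)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise NumericalError(f"MLE optimisation failed: {res.message}")
        t_hat = float(res.x)
        width = hi - lo
        if t_hat <= lo + 1e-3 * width and lo > math.log(1e-8):
            lo, hi = lo - width, lo + 0.1 * width
        elif t_hat >= hi - 1e-3 * width:
            lo, hi = hi - 0.1 * width, hi + width
            if hi > math.log(1e9):
                raise NumericalError("MLE diverged beyond m = 1e9")
        else:
            break
    else:
        raise NumericalError("MLE bracket expansion did not converge")
    m_hat = math.exp(t_hat)

    ll_max = ll(m_hat)
    target = ll_max - drop

    lo_b = max(m_hat * 1e-6, 1e-12)
    if ll(lo_b) >= target:
        ci_low_m = 0.0
    else:
        ci_low_m = float(optimize.brentq(lambda m: ll(m) - target, lo_b, m_hat, rtol=1e-10))
    hi_b = m_hat * 2.0
    while ll(hi_b) > target:
        hi_b *= 2.0
        if hi_b > 1e9:
            raise NumericalError("upper profile bound beyond m = 1e9")
    ci_high_m = float(optimize.brentq(lambda m: ll(m) - target, m_hat, hi_b, rtol=1e-10))

    return RateEstimate(
        m_hat=m_hat,
        mu_hat=rate_per_cell(m_hat, cs.Nt),
        ci_low=rate_per_cell(ci_low_m, cs.Nt),
        ci_high=rate_per_cell(ci_high_m, cs.Nt),
        method="mle",
        n_cultures=n,
        Nt=cs.Nt,
        strain_id=cs.strain_id,
        reporter=cs.reporter,
        level=level,
        loglik=ll_max,
    )


def estimate_auto(cs: CultureSet, level: float = 0.95) -> RateEstimate:
    """Median method when the median count is >= 1, else p0, else m = 0."""
    if float(np.median(cs.counts)) >= 1:
        return estimate_median_lc(cs, level=level)
    if np.all(cs.counts == 0):
        return estimate_mle(cs, level=level)  # boundary case m = 0
    return estimate_p0(cs, level=level)


_ESTIMATORS = {
    "median_lc": estimate_median_lc,
    "p0": estimate_p0,
    "mle": estimate_mle,
    "auto": estimate_auto,
}


# ---------------------------------------------------------------------------
# model object


class FluctuationModel:
    """A fluctuation experiment ready to be fitted.

    Examples
    --------
    >>> model = FluctuationModel([3, 0, 12, 5, 1, 7], Nt=1e8)
    >>> result = model.fit(method="mle")
    >>> print(result.summary())              # doctest: +SKIP
    """

    def __init__(
        self,
        counts,
        Nt: float,
        plated_fraction: float = 1.0,
        strain_id: str = "",
        reporter: str = "",
    ) -> None:
        self.data = CultureSet(
            strain_id=strain_id,
            reporter=reporter,
            counts=np.asarray(counts),
            Nt=Nt,
            plated_fraction=plated_fraction,
        )

    @classmethod
    def from_cultureset(cls, cs: CultureSet) -> "FluctuationModel":
        model = cls.__new__(cls)
        model.data = cs
        return model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, strain_id: str | None = None, reporter: str | None = None
    ) -> "FluctuationModel":
        """Build from a tidy table with the standard culture columns."""
        sub = df
        if strain_id is not None:
            sub = sub[sub["strain_id"] == strain_id]
        if reporter is not None:
            sub = sub[sub["reporter"] == reporter]
        if sub.empty:
            raise ValidationError("no rows match the requested strain/reporter")
        groups = sub.groupby(["strain_id", "reporter"])
        if groups.ngroups != 1:
            raise ValidationError(
                "data frame contains multiple (strain_id, reporter) groups; "
                "specify strain_id/reporter"
            )
        (sid, rep), rows = next(iter(groups))
        nt = rows["Nt"].unique()
        pf = rows["plated_fraction"].unique() if "plated_fraction" in rows else [1.0]
        if len(nt) != 1:
            raise ValidationError(f"{sid}/{rep}: Nt varies within the experiment")
        if len(pf) != 1:
            raise ValidationError(f"{sid}/{rep}: plated_fraction varies within the experiment")
        cs = CultureSet(
            strain_id=str(sid),
            reporter=str(rep),
            counts=rows["mutant_count"].to_numpy(),
            Nt=float(nt[0]),
            plated_fraction=float(pf[0]),
        )
        return cls.from_cultureset(cs)

    @property
    def counts(self) -> np.ndarray:
        return self.data.counts

    def loglik(self, m: float, jackpot_cap: int | None = DEFAULT_JACKPOT_CAP) -> float:
        return ld_loglik(self.data.counts, m, censor_at=jackpot_cap)

    def pmf(self, m: float, r_max: int | None = None):
        if r_max is None:
            r_max = int(min(self.data.counts.max(), DEFAULT_JACKPOT_CAP))
        return ld_pmf(m, r_max)

    def fit(self, method: str = "mle", level: float = 0.95, **kwargs) -> RateEstimate:
        try:
            estimator = _ESTIMATORS[method]
        except KeyError:
            raise ValidationError(
                f"unknown method {method!r}; choose from {sorted(_ESTIMATORS)}"
            ) from None
        return estimator(self.data, level=level, **kwargs)
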