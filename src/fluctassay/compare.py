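"""Strain-vs-strain inference.

Significance of rate differences uses the Wilcoxon-Mann-Whitney rank-sum
test on the culture-level values (mutant counts when the two experiments
share the same final population size, per-culture frequencies otherwise —
ranks are invariant to the common scale, so the choice is immaterial at
shared Nt). Fold changes and derived quantities (dominance ratio, synergy
interaction index) get percentile bootstrap intervals, resampling cultures
— the independent experimental unit — with replacement.

Bootstrap streams are keyed by each experiment's (strain_id, reporter)
label, so a comparison is reproducible under a fixed seed and the synergy
test is exactly symmetric under transposition of the two single mutants.

Synergy follows the standard multiplicative epistasis convention for
mutation rates: the null expectation for the double mutant's fold over
wild type is the product of the single-mutant folds, and the interaction
index is observed/expected. ``synergistic`` requires the index interval to
exclude 1 from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seeds import rng_for
from .data import CultureSet
from .estimate import _ESTIMATORS, lea_coulson_m
from .exceptions import (
    MethodInapplicableError,
    UndefinedFoldError,
    ValidationError,
)

__all__ = [
    "ComparisonResult",
    "DominanceResult",
    "SynergyResult",
    "rank_sum_test",
    "fold_change",
    "classify_mutator",
    "dominance_analysis",
    "synergy_test",
    "interaction_index",
]

DEFAULT_N_BOOT = 2000

#: Dominance call thresholds on the heterozygote/homozygote rate ratio CI.
DOMINANT_LOWER_BOUND = 0.75
SEMIDOMINANT_RATIO = 0.5


@dataclass
class ComparisonResult:
    """Fold change of a strain against a reference strain."""

    strain_id: str
    reference_id: str
    fold: float
    fold_ci: tuple[float, float]
    p_value: float
    is_mutator: bool
    alpha: float = 0.05
    exceeds_exo_null: bool | None = None

    def to_dict(self) -> dict:
        low, high = self.fold_ci
        return {
            "strain_id": self.strain_id,
            "reference_id": self.reference_id,
            "fold": self.fold,
            "fold_ci_low": low,
            "fold_ci_high": high,
            "p_value": self.p_value,
            "is_mutator": self.is_mutator,
            "exceeds_exo_null": self.exceeds_exo_null,
        }


@dataclass
class DominanceResult:
    """Heterozygote/homozygote comparison against a wild-type diploid."""

    strain_id: str
    het_fold: float
    hom_fold: float
    ratio: float
    ratio_ci: tuple[float, float]
    het_p_value: float
    call: str

    def to_dict(self) -> dict:
        low, high = self.ratio_ci
        return {
            "strain_id": self.strain_id,
            "het_fold": self.het_fold,
            "hom_fold": self.hom_fold,
            "ratio": self.ratio,
            "ratio_ci_low": low,
            "ratio_ci_high": high,
            "het_p_value": self.het_p_value,
            "call": self.call,
        }


@dataclass
class SynergyResult:
    """Double-mutant epistasis against the multiplicative null."""

    a_id: str
    b_id: str
    ab_id: str
    fold_a: float
    fold_b: float
    fold_ab: float
    expected_multiplicative: float
    interaction_index: float
    index_ci: tuple[float, float]
    call: str

    def to_dict(self) -> dict:
        low, high = self.index_ci
        return {
            "a_id": self.a_id,
            "b_id": self.b_id,
            "ab_id": self.ab_id,
            "fold_a": self.fold_a,
            "fold_b": self.fold_b,
            "fold_ab": self.fold_ab,
            "expected_multiplicative": self.expected_multiplicative,
            "interaction_index": self.interaction_index,
            "index_ci_low": low,
            "index_ci_high": high,
            "call": self.call,
        }


# ---------------------------------------------------------------------------
# rank-sum test


def rank_sum_test(x, y, alternative: str = "two-sided", method: str = "auto") -> float:
    """Wilcoxon-Mann-Whitney p-value for two samples of counts or rates.

    With ``method="auto"`` the exact U distribution is enumerated when both
    samples have n <= 12 and the pooled data are tie-free; otherwise the
    normal approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size <= 12 and y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# point and bootstrap rate estimation helpers


def _point_mu(cs: CultureSet, estimator: str = "auto") -> float:
    try:
        fit = _ESTIMATORS[estimator]
    except KeyError:
        raise ValidationError(f"unknown estimator {estimator!r}") from None
    return fit(cs).mu_hat


def _m_from_resample(sample_matrix: np.ndarray) -> np.ndarray:
    """Vectorised auto estimator over bootstrap resamples (rows)."""
    med = np.median(sample_matrix, axis=1)
    zero_frac = np.mean(sample_matrix == 0, axis=1)
    m = np.zeros(sample_matrix.shape[0])
    lc_mask = med >= 1
    if lc_mask.any():
        uniq, inverse = np.unique(med[lc_mask], return_inverse=True)
        solved = np.array([lea_coulson_m(float(u)) for u in uniq])
        m[lc_mask] = solved[inverse]
    p0_mask = ~lc_mask & (zero_frac < 1.0)
    m[p0_mask] = -np.log(zero_frac[p0_mask])
    # remaining rows are all-zero resamples: m = 0
    return m


def _bootstrap_mu(cs: CultureSet, n_boot: int, seed: int) -> np.ndarray:
    rng = rng_for(seed, cs.strain_id, cs.reporter, "bootstrap")
    n = cs.counts.size
    idx = rng.integers(0, n, size=(n_boot, n))
    return _m_from_resample(cs.counts[idx]) / cs.Nt


def _culture_values(cs: CultureSet, ref: CultureSet):
    """Values fed to the rank-sum test: counts at shared Nt, else frequencies."""
    if cs.Nt == ref.Nt:
        return cs.counts, ref.counts
    return cs.counts / cs.Nt, ref.counts / ref.Nt


def _percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValidationError("no finite bootstrap replicates")
    alpha2 = 100.0 * (1.0 - level) / 2.0
    return (
        float(np.percentile(finite, alpha2)),
        float(np.percentile(finite, 100.0 - alpha2)),
    )


# ---------------------------------------------------------------------------
# fold change and mutator classification


def fold_change(
    cs: CultureSet,
    ref: CultureSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    estimator: str = "auto",
    alpha: float = 0.05,
    level: float = 0.95,
) -> ComparisonResult:
    """Rate fold change of ``cs`` over ``ref`` with a bootstrap CI.

    Cultures are resampled with replacement within each strain; the CI is
    the percentile interval of the resampled fold. The p-value is the
    two-sided rank-sum test on culture-level values.
    """
    mu_cs = _point_mu(cs, estimator)
    mu_ref = _point_mu(ref, estimator)
    if mu_ref == 0:
        raise UndefinedFoldError(
            f"reference {ref.strain_id}/{ref.reporter} has estimated rate 0; "
            "fold change undefined (compare p0 estimates instead)"
        )
    fold = mu_cs / mu_ref
    boot_cs = _bootstrap_mu(cs, n_boot, seed)
    boot_ref = _bootstrap_mu(ref, n_boot, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_fold = boot_cs / boot_ref
    ci = _percentile_ci(boot_fold, level)
    p = rank_sum_test(*_culture_values(cs, ref))
    return ComparisonResult(
        strain_id=cs.strain_id,
        reference_id=ref.strain_id,
        fold=fold,
        fold_ci=ci,
        p_value=p,
        is_mutator=bool(p < alpha and fold > 1),
        alpha=alpha,
    )


def classify_mutator(result: ComparisonResult, alpha: float = 0.05) -> bool:
    """True iff significantly elevated: p < alpha and fold > 1."""
    return bool(result.p_value < alpha and result.fold > 1)


# ---------------------------------------------------------------------------
# dominance


def dominance_analysis(
    wt_dip: CultureSet,
    het: CultureSet,
    hom: CultureSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    estimator: str = "auto",
    alpha: float = 0.05,
    level: float = 0.95,
) -> DominanceResult:
    """Classify a diploid allele as recessive, semidominant or dominant.

    The heterozygote/homozygote rate ratio is ~0.5 for a semidominant
    allele (each gene copy contributing equally). Calls: ``recessive`` when
    the heterozygote is not significantly above the wild-type diploid;
    ``dominant`` when the ratio CI lies above 0.75; ``semidominant``
    otherwise (the typical case being a ratio CI containing 0.5).
    """
    mu_wt = _point_mu(wt_dip, estimator)
    mu_het = _point_mu(het, estimator)
    mu_hom = _point_mu(hom, estimator)
    if mu_hom == 0:
        raise UndefinedFoldError(
            f"homozygote {hom.strain_id} has estimated rate 0; ratio undefined"
        )
    if mu_wt == 0:
        raise UndefinedFoldError(
            f"wild-type diploid {wt_dip.strain_id} has estimated rate 0; folds undefined"
        )
    het_fold = mu_het / mu_wt
    hom_fold = mu_hom / mu_wt
    ratio = mu_het / mu_hom
    boot_het = _bootstrap_mu(het, n_boot, seed)
    boot_hom = _bootstrap_mu(hom, n_boot, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_ci = _percentile_ci(boot_het / boot_hom, level)
    het_p = rank_sum_test(*_culture_values(het, wt_dip))
    if not (het_p < alpha and het_fold > 1):
        call = "recessive"
    elif ratio_ci[0] > DOMINANT_LOWER_BOUND:
        call = "dominant"
    else:
        call = "semidominant"
    return DominanceResult(
        strain_id=het.strain_id,
        het_fold=het_fold,
        hom_fold=hom_fold,
        ratio=ratio,
        ratio_ci=ratio_ci,
        het_p_value=het_p,
        call=call,
    )


# ---------------------------------------------------------------------------
# synergy


def interaction_index(fold_a: float, fold_b: float, fold_ab: float) -> float:
    """Observed double-mutant fold over the multiplicative expectation."""
    if fold_a <= 0 or fold_b <= 0:
        raise ValidationError("single-mutant folds must be positive")
    return fold_ab / (fold_a * fold_b)


def synergy_test(
    wt: CultureSet,
    a_only: CultureSet,
    b_only: CultureSet,
    ab: CultureSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    estimator: str = "auto",
    level: float = 0.95,
) -> SynergyResult:
    """Test a double mutant against the multiplicative null.

    Bootstraps all four strains jointly; ``synergistic`` iff the interaction
    index CI lower bound exceeds 1, ``sub-multiplicative`` iff the upper
    bound is below 1, ``multiplicative`` otherwise.
    """
    arms = {"wt": wt, "a_only": a_only, "b_only": b_only, "ab": ab}
    mus = {}
    for name, arm in arms.items():
        try:
            mus[name] = _point_mu(arm, estimator)
        except (MethodInapplicableError, ValidationError) as exc:
            raise ValidationError(
                f"arm {name!r} ({arm.strain_id}/{arm.reporter}) is not estimable: {exc}"
            ) from exc
    if mus["wt"] == 0:
        raise UndefinedFoldError(f"wild type {wt.strain_id} has estimated rate 0")
    fold_a = mus["a_only"] / mus["wt"]
    fold_b = mus["b_only"] / mus["wt"]
    fold_ab = mus["ab"] / mus["wt"]
    index = interaction_index(fold_a, fold_b, fold_ab)

    boot = {name: _bootstrap_mu(arm, n_boot, seed) for name, arm in arms.items()}
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_index = (boot["ab"] * boot["wt"]) / (boot["a_only"] * boot["b_only"])
    ci = _percentile_ci(boot_index, level)
    if ci[0] > 1.0:
        call = "synergistic"
    elif ci[1] < 1.0:
        call = "sub-multiplicative"
    else:
        call = "multiplicative"
    return SynergyResult(
        a_id=a_only.strain_id,
        b_id=b_only.strain_id,
        ab_id=ab.strain_id,
        fold_a=fold_a,
        fold_b=fold_b,
        fold_ab=fold_ab,
        expected_multiplicative=fold_a * fold_b,
        interaction_index=index,
        index_ci=ci,
        call=call,
    )
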