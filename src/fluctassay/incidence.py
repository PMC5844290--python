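"""Tumor variant-incidence statistics.

Each variant's frequency is its number of documented occurrences divided
by the number of tumors in which the variant's exon was sequenced (the
denominators differ by exon because many studies sequence only selected
exons). Data from several studies or cancer types are combined by summing
numerators and denominators. Pairwise frequency differences use Fisher's
exact test (two-sided, summing all tables at fixed margins no more
probable than the observed one); the association between a variant's
mutator strength (fold increase over wild type) and its tumor frequency
is summarised by the Spearman rank correlation on the log-log scale, with
an exact permutation p-value for small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "VariantIncidence",
    "AssociationResult",
    "variant_frequency",
    "combine_incidence",
    "fisher_exact_2x2",
    "pairwise_variant_tests",
    "rate_frequency_association",
]

#: Exact permutation p-values are enumerated up to this many pairs (9! ~ 3.6e5).
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class VariantIncidence:
    """Occurrence count and sequencing denominator for one variant."""

    variant_id: str
    occurrences: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValidationError(f"{self.variant_id}: denominator must be positive")
        if not (0 <= self.occurrences <= self.denominator):
            raise ValidationError(
                f"{self.variant_id}: need 0 <= occurrences <= denominator, "
                f"got {self.occurrences}/{self.denominator}"
            )

    @property
    def frequency(self) -> float:
        return self.occurrences / self.denominator


@dataclass(frozen=True)
class AssociationResult:
    """Rank correlation between mutator strength and tumor frequency."""

    rho: float
    p_value: float
    n: int
    method: str  # "spearman_exact" or "spearman_asymptotic"


def variant_frequency(n_v: int, N_v: int) -> float:
    """Frequency ``n_v / N_v`` of a variant among sequenced tumors."""
    return VariantIncidence("", int(n_v), int(N_v)).frequency


def combine_incidence(*parts: VariantIncidence, variant_id: str | None = None) -> VariantIncidence:
    """Pool studies/cancer types by summing numerators and denominators."""
    if not parts:
        raise ValidationError("nothing to combine")
    if variant_id is None:
        ids = {p.variant_id for p in parts}
        if len(ids) != 1:
            raise ValidationError(f"refusing to pool distinct variants {sorted(ids)}")
        variant_id = parts[0].variant_id
    return VariantIncidence(
        variant_id=variant_id,
        occurrences=sum(p.occurrences for p in parts),
        denominator=sum(p.denominator for p in parts),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table.

    The two-sided p is the total hypergeometric probability of all tables
    with the observed margins that are no more probable than the observed
    table (the common convention).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)) or np.any(arr != np.floor(arr)) or np.any(arr < 0):
        raise ValidationError("table cells must be non-negative integers")
    if arr.sum() == 0:
        raise ValidationError("table must have at least one positive margin")
    return float(stats.fisher_exact(arr.astype(np.int64), alternative="two-sided")[1])


def pairwise_variant_tests(
    variants: list[VariantIncidence], adjust: str | None = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Fisher p-values on variant frequencies.

    Each pair (v, w) is tested on the table
    ``[[n_v, N_v - n_v], [n_w, N_w - n_w]]``. ``adjust="bh"`` applies
    Benjamini-Hochberg across the off-diagonal pairs (the default reports
    raw p-values).
    """
    if len(variants) < 2:
        raise ValidationError("need at least two variants")
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValidationError("variant ids must be unique")
    k = len(variants)
    p = np.ones((k, k))
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        v, w = variants[i], variants[j]
        raw.append(
            fisher_exact_2x2(
                [
                    [v.occurrences, v.denominator - v.occurrences],
                    [w.occurrences, w.denominator - w.occurrences],
                ]
            )
        )
    if adjust is not None:
        if adjust.lower() not in ("bh", "fdr_bh", "benjamini-hochberg"):
            raise ValidationError(f"unknown adjustment {adjust!r}; only 'bh' is supported")
        raw = list(stats.false_discovery_control(raw, method="bh"))
    for (i, j), pv in zip(pairs, raw):
        p[i, j] = p[j, i] = pv
    return pd.DataFrame(p, index=ids, columns=ids)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for |rho| by full n! enumeration."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (cy[perms] @ cx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def rate_frequency_association(folds, freqs) -> AssociationResult:
    """Spearman correlation of log fold-increase with log tumor frequency.

    Requires at least 3 strictly positive pairs. For n <= 9 the p-value is
    the exact two-sided permutation probability; beyond that, the
    asymptotic p from the rank correlation is used. (The rank correlation
    itself is invariant to the log transform; the transform matters only
    for plotting and the Pearson alternative.)
    """
    folds = np.asarray(folds, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if folds.shape != freqs.shape or folds.ndim != 1:
        raise ValidationError("folds and freqs must be equal-length 1-D vectors")
    n = folds.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.any(folds <= 0) or np.any(freqs <= 0):
        raise ValidationError("folds and freqs must be strictly positive for the log scale")
    x = np.log(folds)
    y = np.log(freqs)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("degenerate (constant) input")
    rho, p_asym = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman_exact"
    else:
        p = float(p_asym)
        method = "spearman_asymptotic"
    return AssociationResult(rho=rho, p_value=p, n=n, method=method)
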