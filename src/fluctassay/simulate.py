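"""Synthetic fluctuation-assay data with Luria-Delbrueck statistical structure.

The generative model is the exact twin of :mod:`fluctassay.distribution`:
each culture experiences ``M ~ Poisson(mu * (Nt - N0))`` mutation events,
and each event founds a clone whose final size is drawn from the
Lea-Coulson law ``P(C = k) = 1/(k(k+1))`` by inverse transform
(``C = floor(1/U)``, ``U`` uniform on (0,1)), truncated at ``Nt``. The
mutant count is the clone-size sum, optionally binomially thinned when
only a fraction of the culture is plated.

``paper_panel`` builds a multi-strain study design emulating a mutator
survey in yeast: a wild type, an exonuclease-null benchmark, variant
mutators spanning ~2x to ~100x, a diploid wild-type/heterozygote/homozygote
trio (heterozygote at the midpoint of wild type and homozygote), and a
mismatch-repair-null (MMR-null) arm in which one variant synergises with
the MMR defect while two behave as neutral passengers.

``exact_growth_oracle`` is a deliberately small-scale, mechanistically
independent generative model (explicit binary fission, per-daughter
mutation, mutant lineages breeding true) used to validate the compound
draw at matched means.
"""

from __future__ import annotations

import numpy as np

from ._seeds import rng_for, seed_sequence_for
from .data import CultureSet, StrainSpec
from .exceptions import DomainError, ValidationError

__all__ = [
    "simulate_culture",
    "simulate_cultureset",
    "simulate_experiment",
    "exact_growth_oracle",
    "exact_growth_sample",
    "paper_panel",
    "expected_clone_size",
]

#: Refuse simulations whose expected event count would make jackpot
#: tabulation intractable downstream.
MAX_EXPECTED_EVENTS = 1e6

#: Largest generation count accepted by the exhaustive growth oracle.
MAX_ORACLE_GENERATIONS = 14


def _draw_counts(m: float, n: int, Nt: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draw of ``n`` culture counts at event mean ``m``."""
    events = rng.poisson(m, size=n)
    total = int(events.sum())
    if total == 0:
        return np.zeros(n, dtype=np.int64)
    u = rng.random(total)
    with np.errstate(divide="ignore"):
        sizes = np.floor(1.0 / u)
    sizes = np.minimum(sizes, Nt)
    owner = np.repeat(np.arange(n), events)
    counts = np.bincount(owner, weights=sizes, minlength=n)
    return counts.astype(np.int64)


def _check_spec(spec: StrainSpec) -> None:
    if spec.mu * spec.Nt > MAX_EXPECTED_EVENTS:
        raise DomainError(
            f"{spec.strain_id}: mu*Nt = {spec.mu * spec.Nt:g} exceeds "
            f"{MAX_EXPECTED_EVENTS:g}; simulated jackpots would exceed tabulation limits"
        )


def simulate_culture(spec: StrainSpec, seed: int) -> int:
    """Draw the mutant count of a single culture."""
    _check_spec(spec)
    rng = rng_for(seed, spec.strain_id, spec.reporter, "single")
    count = _draw_counts(spec.m, 1, spec.Nt, rng)[0]
    if spec.plated_fraction < 1.0:
        count = rng.binomial(count, spec.plated_fraction)
    return int(count)


def simulate_cultureset(spec: StrainSpec, seed: int) -> CultureSet:
    """Draw all ``spec.n_cultures`` cultures of one strain x reporter."""
    _check_spec(spec)
    rng = rng_for(seed, spec.strain_id, spec.reporter)
    counts = _draw_counts(spec.m, spec.n_cultures, spec.Nt, rng)
    if spec.plated_fraction < 1.0:
        counts = rng.binomial(counts, spec.plated_fraction)
    return CultureSet(
        strain_id=spec.strain_id,
        reporter=spec.reporter,
        counts=counts,
        Nt=spec.Nt,
        plated_fraction=spec.plated_fraction,
    )


def simulate_experiment(panel: list[StrainSpec], seed: int) -> list[CultureSet]:
    """Simulate every strain of a panel.

    Per-strain child seeds derive deterministically from the master seed by
    stable hashing of (strain_id, reporter), so extending the panel leaves
    existing strains' draws untouched.
    """
    if not panel:
        raise ValidationError("panel must be non-empty")
    keys = [(s.strain_id, s.reporter) for s in panel]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (strain_id, reporter) pairs: {dupes}")
    return [simulate_cultureset(spec, seed) for spec in panel]


def exact_growth_oracle(mu: float, generations: int, seed: int) -> int:
    """Mutant count from explicit binary fission of one founder cell.

    Every division produces two daughters, each independently mutating with
    probability ``mu``; mutant lineages breed true. Limited to
    ``generations <= 14`` (final population 2^14 = 16384 cells) because the
    oracle is deliberately small-scale.
    """
    return int(exact_growth_sample(mu, generations, 1, seed)[0])


def exact_growth_sample(mu: float, generations: int, n: int, seed: int) -> np.ndarray:
    """Vectorised replicates of :func:`exact_growth_oracle`."""
    if generations > MAX_ORACLE_GENERATIONS:
        raise DomainError(
            f"generations must be <= {MAX_ORACLE_GENERATIONS} (exhaustive oracle)"
        )
    if generations < 0:
        raise DomainError("generations must be >= 0")
    if not (0 <= mu <= 1):
        raise DomainError("mu must be a probability in [0, 1]")
    rng = rng_for(seed, "growth-oracle")
    nonmut = np.full(n, 1, dtype=np.int64)
    mut = np.zeros(n, dtype=np.int64)
    for _ in range(generations):
        daughters = 2 * nonmut
        new_mut = rng.binomial(daughters, mu)
        nonmut = daughters - new_mut
        mut = 2 * mut + new_mut
    return mut


def expected_clone_size(Nt: float) -> float:
    """Mean of the truncated clone-size draw ``min(C, Nt)``.

    Truncation lumps the tail mass ``P(C >= Nt) = 1/Nt`` at ``Nt``, so the
    mean is the harmonic number ``H_Nt = sum_{k=1..Nt} 1/k``.
    """
    K = int(Nt)
    if K <= 2e6:
        return float(np.sum(1.0 / np.arange(1, K + 1)))
    euler_gamma = 0.5772156649015329
    return float(np.log(K) + euler_gamma + 1.0 / (2 * K))


def paper_panel(
    mu_wt: float = 3e-8,
    Nt: float = 1e8,
    N0: float = 1e3,
    n_cultures: int = 18,
    reporter: str = "CanR",
    exo_null_fold: float = 7.0,
    variant_folds: dict[str, float] | None = None,
    hom_fold: float = 40.0,
    mmr_null_fold: float = 25.0,
    synergist_alone_fold: float = 3.0,
    synergy_interaction: float = 10.0,
) -> list[StrainSpec]:
    """Strain panel emulating a cancer-variant mutator survey in yeast.

    Defaults: wild-type forward-mutation rate 3e-8 per cell (m = 3 events
    per culture at Nt = 1e8); exonuclease-null benchmark at 7x wild type;
    variant mutators at 2x / 6x / 20x / 100x; a diploid trio with the
    heterozygote at the midpoint of wild type and homozygote (semidominance);
    and an MMR arm where the MMR deletion alone is 25x, one weak variant
    (3x alone) synergises with it (interaction index 10), and two variants
    are neutral passengers (interaction index 1).
    """
    if variant_folds is None:
        variant_folds = {
            "pol2-2x": 2.0,
            "pol2-weak": 6.0,
            "pol2-moderate": 20.0,
            "pol2-strong": 100.0,
        }

    def spec(strain_id, fold, ploidy="haploid", mmr="proficient", n=n_cultures):
        return StrainSpec(
            strain_id=strain_id,
            reporter=reporter,
            mu=mu_wt * fold,
            Nt=Nt,
            N0=N0,
            n_cultures=n,
            ploidy_config=ploidy,
            mmr_status=mmr,
            true_fold=fold,
        )

    panel = [spec("WT", 1.0), spec("pol2-exo-null", exo_null_fold)]
    panel += [spec(name, fold) for name, fold in variant_folds.items()]

    het_fold = (1.0 + hom_fold) / 2.0
    panel += [
        spec("WT/WT", 1.0, ploidy="hom_diploid"),
        spec("pol2-strong/WT", het_fold, ploidy="het_diploid"),
        spec("pol2-strong/pol2-strong", hom_fold, ploidy="hom_diploid"),
    ]

    panel += [
        spec("mlh1", mmr_null_fold, mmr="null"),
        spec("pol2-syn", synergist_alone_fold),
        spec(
            "pol2-syn mlh1",
            synergist_alone_fold * mmr_null_fold * synergy_interaction,
            mmr="null",
        ),
        spec("pol2-neutral-1", 1.0),
        spec("pol2-neutral-1 mlh1", mmr_null_fold, mmr="null"),
        spec("pol2-neutral-2", 1.0),
        spec("pol2-neutral-2 mlh1", mmr_null_fold, mmr="null"),
    ]
    return panel


def child_seed(seed: int, strain_id: str, reporter: str) -> np.random.SeedSequence:
    """Expose the per-strain seed derivation (for diagnostics/logging)."""
    return seed_sequence_for(seed, strain_id, reporter)
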