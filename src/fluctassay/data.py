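"""Core data containers shared across the pipeline.

``CultureSet`` holds one fluctuation experiment (one strain x one reporter
locus): the per-culture mutant colony counts, the final viable cell number
per culture and the fraction of each culture plated on selective medium.
``StrainSpec`` describes a strain configuration for the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FewCulturesWarning, ValidationError

#: Conventional minimum number of parallel cultures per experiment.
MIN_CULTURES = 18

PLOIDY_CONFIGS = ("haploid", "het_diploid", "hom_diploid")
MMR_STATUSES = ("proficient", "null")


@dataclass
class CultureSet:
    """Mutant counts from parallel cultures of one strain at one reporter.

    Parameters
    ----------
    strain_id, reporter : str
        Labels identifying the strain and the mutagenesis reporter locus
        (e.g. a forward-mutation locus such as CAN1, or a frameshift
        reversion locus).
    counts : array of int
        Mutant colony count per culture, non-negative.
    Nt : float
        Final viable cells per culture.
    plated_fraction : float
        Fraction of each culture plated on selective medium, in (0, 1].
    """

    strain_id: str
    reporter: str
    counts: np.ndarray
    Nt: float
    plated_fraction: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        flt = np.asarray(arr, dtype=float)
        if arr.size < 1:
            raise ValidationError(f"{self._label}: at least one culture required")
        if not np.all(np.isfinite(flt)) or np.any(flt != np.floor(flt)) or np.any(flt < 0):
            raise ValidationError(f"{self._label}: counts must be non-negative integers")
        self.counts = flt.astype(np.int64)
        if not (np.isfinite(self.Nt) and self.Nt > 0):
            raise ValidationError(f"{self._label}: Nt must be positive")
        if not (0 < self.plated_fraction <= 1):
            raise ValidationError(f"{self._label}: plated_fraction must be in (0, 1]")
        if self.n_cultures < MIN_CULTURES:
            warnings.warn(
                f"{self._label}: only {self.n_cultures} cultures "
                f"(convention is >= {MIN_CULTURES})",
                FewCulturesWarning,
                stacklevel=2,
            )

    @property
    def _label(self) -> str:
        return f"{self.strain_id}/{self.reporter}"

    @property
    def n_cultures(self) -> int:
        return int(np.asarray(self.counts).size)


@dataclass(frozen=True)
class StrainSpec:
    """Configuration of one simulated strain x reporter experiment.

    ``mu`` is the true mutation rate per cell per division; cultures grow
    from ``N0`` to ``Nt`` cells so the expected number of mutation events
    per culture is ``m = mu * (Nt - N0)``.
    """

    strain_id: str
    reporter: str
    mu: float
    Nt: float = 1e8
    N0: float = 1e3
    n_cultures: int = MIN_CULTURES
    ploidy_config: str = "haploid"
    mmr_status: str = "proficient"
    plated_fraction: float = 1.0
    #: optional bookkeeping: configured fold vs the panel's wild type
    true_fold: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.mu < 1e-3):
            raise ValidationError(f"{self.strain_id}: mu must be in [0, 1e-3), got {self.mu}")
        if not (1 <= self.N0 < self.Nt):
            raise ValidationError(f"{self.strain_id}: need 1 <= N0 < Nt")
        if self.n_cultures < 1:
            raise ValidationError(f"{self.strain_id}: n_cultures must be >= 1")
        if self.ploidy_config not in PLOIDY_CONFIGS:
            raise ValidationError(f"{self.strain_id}: unknown ploidy_config {self.ploidy_config!r}")
        if self.mmr_status not in MMR_STATUSES:
            raise ValidationError(f"{self.strain_id}: unknown mmr_status {self.mmr_status!r}")
        if not (0 < self.plated_fraction <= 1):
            raise ValidationError(f"{self.strain_id}: plated_fraction must be in (0, 1]")

    @property
    def m(self) -> float:
        """Expected mutation events per culture."""
        return self.mu * (self.Nt - self.N0)
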