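"""End-to-end study orchestration.

A :class:`StudyConfig` (built in code or loaded from YAML/JSON) names the
input — either a culture table on disk or a simulation panel — plus the
reference strain, the estimator, test settings and the structured analyses
(dominance trios, synergy quartets, optional variant-incidence table).
:func:`run_pipeline` runs, in order: rate estimation for every experiment,
fold-change comparisons against the reference (and against an
exonuclease-null benchmark when configured), dominance and synergy
analyses, and the incidence arm, and returns tidy tables plus a
human-readable summary. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .compare import dominance_analysis, fold_change, synergy_test
from .data import CultureSet, StrainSpec
from .estimate import _ESTIMATORS
from .exceptions import FluctAssayError, ValidationError
from .incidence import pairwise_variant_tests, rate_frequency_association
from .io import cultures_to_frame, read_cultures, read_variants, write_cultures
from .simulate import paper_panel, simulate_experiment

logger = logging.getLogger("fluctassay")

__all__ = ["StudyConfig", "PipelineReport", "run_pipeline", "build_panel"]


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    seed: int = 0
    estimator: str = "auto"
    alpha: float = 0.05
    n_boot: int = 2000
    #: either a path to a culture TSV ...
    input: str | None = None
    #: ... or a simulation block: {"preset": "paper_panel", ...overrides}
    #: or {"panel": [ {strain spec fields...}, ... ]}
    simulate: dict | None = None
    reference: str = "WT"
    exo_null: str | None = None
    dominance: list[dict] = field(default_factory=list)
    synergy: list[dict] = field(default_factory=list)
    incidence: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.estimator not in _ESTIMATORS:
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if (self.input is None) == (self.simulate is None):
            raise ValidationError("exactly one of 'input' or 'simulate' must be given")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


@dataclass
class PipelineReport:
    """Tidy result tables plus a human-readable summary."""

    cultures: list[CultureSet]
    rates: pd.DataFrame
    comparisons: pd.DataFrame
    dominance: pd.DataFrame
    synergy: pd.DataFrame
    incidence_frequencies: pd.DataFrame
    incidence_pairwise: pd.DataFrame
    summary: str

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cultures(self.cultures, out / "cultures.tsv")
        for name, df in [
            ("rates", self.rates),
            ("comparisons", self.comparisons),
            ("dominance", self.dominance),
            ("synergy", self.synergy),
            ("incidence_frequencies", self.incidence_frequencies),
            ("incidence_pairwise", self.incidence_pairwise),
        ]:
            if not df.empty:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(self.summary + "\n")


def build_panel(block: dict) -> list[StrainSpec]:
    """Materialise the simulation block of a config into strain specs."""
    if "preset" in block:
        preset = block["preset"]
        if preset != "paper_panel":
            raise ValidationError(f"unknown preset {preset!r}")
        kwargs = {k: v for k, v in block.items() if k != "preset"}
        return paper_panel(**kwargs)
    if "panel" in block:
        return [StrainSpec(**entry) for entry in block["panel"]]
    raise ValidationError("simulate block needs either 'preset' or 'panel'")


def _find(cultures: list[CultureSet], strain_id: str, reporter: str) -> CultureSet:
    for cs in cultures:
        if cs.strain_id == strain_id and cs.reporter == reporter:
            return cs
    raise ValidationError(f"strain {strain_id!r} (reporter {reporter!r}) not found")


def run_pipeline(config: StudyConfig) -> PipelineReport:
    # --- stage: input -----------------------------------------------------
    if config.simulate is not None:
        panel = build_panel(config.simulate)
        cultures = simulate_experiment(panel, config.seed)
        logger.info("simulated %d experiments (seed %d)", len(cultures), config.seed)
    else:
        cultures = read_cultures(config.input)
        logger.info("read %d experiments from %s", len(cultures), config.input)

    # --- stage: rates -----------------------------------------------------
    estimator = _ESTIMATORS[config.estimator]
    rates = []
    estimates = {}
    for cs in cultures:
        try:
            est = estimator(cs)
        except FluctAssayError as exc:
            raise type(exc)(f"rate estimation failed for {cs.strain_id}/{cs.reporter}: {exc}")
        estimates[(cs.strain_id, cs.reporter)] = est
        rates.append(est.to_dict())
        logger.info(
            "rate %s/%s: m=%.4g mu=%.4g [%s]",
            cs.strain_id, cs.reporter, est.m_hat, est.mu_hat, est.method,
        )
    rates_df = pd.DataFrame(rates)

    # --- stage: comparisons vs reference ---------------------------------
    reporters = sorted({cs.reporter for cs in cultures})
    comparisons = []
    for reporter in reporters:
        group = [cs for cs in cultures if cs.reporter == reporter]
        try:
            ref = _find(group, config.reference, reporter)
        except ValidationError:
            raise ValidationError(
                f"reference strain {config.reference!r} missing for reporter {reporter!r}"
            )
        exo = None
        if config.exo_null is not None:
            exo = _find(group, config.exo_null, reporter)
        for cs in group:
            if cs is ref:
                continue
            res = fold_change(
                cs, ref, n_boot=config.n_boot, seed=config.seed,
                estimator=config.estimator, alpha=config.alpha,
            )
            if exo is not None and cs is not exo:
                vs_exo = fold_change(
                    cs, exo, n_boot=config.n_boot, seed=config.seed,
                    estimator=config.estimator, alpha=config.alpha,
                )
                res.exceeds_exo_null = bool(
                    vs_exo.fold > 1 and vs_exo.p_value < config.alpha
                )
            row = res.to_dict()
            row["reporter"] = reporter
            comparisons.append(row)
    comparisons_df = pd.DataFrame(comparisons)

    # --- stage: dominance -------------------------------------------------
    dominance_rows = []
    for entry in config.dominance:
        reporter = entry.get("reporter", reporters[0])
        group = [cs for cs in cultures if cs.reporter == reporter]
        res = dominance_analysis(
            _find(group, entry["wt"], reporter),
            _find(group, entry["het"], reporter),
            _find(group, entry["hom"], reporter),
            n_boot=config.n_boot, seed=config.seed,
            estimator=config.estimator, alpha=config.alpha,
        )
        row = res.to_dict()
        row["reporter"] = reporter
        dominance_rows.append(row)
    dominance_df = pd.DataFrame(dominance_rows)

    # --- stage: synergy ---------------------------------------------------
    synergy_rows = []
    for entry in config.synergy:
        reporter = entry.get("reporter", reporters[0])
        group = [cs for cs in cultures if cs.reporter == reporter]
        res = synergy_test(
            _find(group, entry["wt"], reporter),
            _find(group, entry["a"], reporter),
            _find(group, entry["b"], reporter),
            _find(group, entry["ab"], reporter),
            n_boot=config.n_boot, seed=config.seed, estimator=config.estimator,
        )
        row = res.to_dict()
        row["reporter"] = reporter
        synergy_rows.append(row)
    synergy_df = pd.DataFrame(synergy_rows)

    # --- stage: incidence -------------------------------------------------
    freq_df = pd.DataFrame()
    pair_df = pd.DataFrame()
    if config.incidence is not None:
        variants = read_variants(config.incidence)
        freq_df = pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in variants],
                "occurrences": [v.occurrences for v in variants],
                "denominator": [v.denominator for v in variants],
                "frequency": [v.frequency for v in variants],
            }
        )
        if len(variants) >= 2:
            pair = pairwise_variant_tests(variants)
            pair_df = pair.reset_index(names="variant_id")

    # --- summary ----------------------------------------------------------
    lines = ["Fluctuation-assay study summary", "=" * 31]
    lines.append(f"experiments: {len(cultures)}; estimator: {config.estimator}; "
                 f"alpha: {config.alpha}; seed: {config.seed}")
    for row in comparisons:
        flag = " *" if row["is_mutator"] else ""
        exo = ""
        if row.get("exceeds_exo_null") is not None:
            exo = "; exceeds exo-null" if row["exceeds_exo_null"] else "; within exo-null range"
        lines.append(
            f"  {row['strain_id']} [{row['reporter']}]: "
            f"{row['fold']:.2f}x vs {row['reference_id']} "
            f"(p={row['p_value']:.3g}){flag}{exo}"
        )
    for row in dominance_rows:
        lines.append(
            f"  dominance {row['strain_id']}: het {row['het_fold']:.1f}x, "
            f"hom {row['hom_fold']:.1f}x, ratio {row['ratio']:.2f} -> {row['call']}"
        )
    for row in synergy_rows:
        lines.append(
            f"  synergy {row['ab_id']}: index {row['interaction_index']:.2f} "
            f"[{row['index_ci_low']:.2f}, {row['index_ci_high']:.2f}] -> {row['call']}"
        )
    summary = "\n".join(lines)

    report = PipelineReport(
        cultures=cultures,
        rates=rates_df,
        comparisons=comparisons_df,
        dominance=dominance_df,
        synergy=synergy_df,
        incidence_frequencies=freq_df,
        incidence_pairwise=pair_df,
        summary=summary,
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
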