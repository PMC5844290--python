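"""Tab-separated readers and writers.

One table dialect throughout: TSV, UTF-8, header row, ``.`` for missing.
Culture tables carry one row per culture with columns
``strain_id, reporter, culture_id, mutant_count, Nt, plated_fraction``;
variant tables carry ``variant_id, exon, occurrences, denominator`` and an
optional ``cancer_type`` column whose rows are pooled per variant.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CultureSet
from .exceptions import ValidationError
from .incidence import VariantIncidence, combine_incidence

__all__ = [
    "CULTURE_COLUMNS",
    "read_cultures",
    "write_cultures",
    "cultures_to_frame",
    "read_variants",
]

CULTURE_COLUMNS = [
    "strain_id",
    "reporter",
    "culture_id",
    "mutant_count",
    "Nt",
    "plated_fraction",
]

VARIANT_COLUMNS = ["variant_id", "exon", "occurrences", "denominator"]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _bad_lines(df: pd.DataFrame, mask: np.ndarray) -> str:
    """File line numbers (header = line 1) of offending rows."""
    lines = (df.index[np.asarray(mask)] + 2).tolist()
    return ", ".join(str(x) for x in lines[:10]) + (", ..." if len(lines) > 10 else "")


def read_cultures(path) -> list[CultureSet]:
    """Read a culture table into validated per-(strain, reporter) sets."""
    df = _read_tsv(path)
    _require_columns(df, CULTURE_COLUMNS, path)

    counts = pd.to_numeric(df["mutant_count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != np.floor(counts.fillna(-1)))
    if bad.any():
        raise ValidationError(
            f"{path}: mutant_count must be a non-negative integer "
            f"(line {_bad_lines(df, bad.to_numpy())})"
        )
    nt = pd.to_numeric(df["Nt"], errors="coerce")
    bad = nt.isna() | (nt <= 0)
    if bad.any():
        raise ValidationError(f"{path}: Nt must be positive (line {_bad_lines(df, bad.to_numpy())})")
    pf = pd.to_numeric(df["plated_fraction"], errors="coerce")
    bad = pf.isna() | (pf <= 0) | (pf > 1)
    if bad.any():
        raise ValidationError(
            f"{path}: plated_fraction must be in (0, 1] (line {_bad_lines(df, bad.to_numpy())})"
        )
    df = df.assign(mutant_count=counts.astype(np.int64), Nt=nt, plated_fraction=pf)

    sets: list[CultureSet] = []
    for (sid, rep), rows in df.groupby(["strain_id", "reporter"], sort=False):
        if rows["Nt"].nunique() != 1:
            raise ValidationError(
                f"{path}: Nt varies within {sid}/{rep}; one final population "
                "size per experiment is required"
            )
        if rows["plated_fraction"].nunique() != 1:
            raise ValidationError(f"{path}: plated_fraction varies within {sid}/{rep}")
        sets.append(
            CultureSet(
                strain_id=str(sid),
                reporter=str(rep),
                counts=rows["mutant_count"].to_numpy(),
                Nt=float(rows["Nt"].iloc[0]),
                plated_fraction=float(rows["plated_fraction"].iloc[0]),
            )
        )
    if not sets:
        raise ValidationError(f"{path}: no culture rows")
    return sets


def cultures_to_frame(sets: list[CultureSet]) -> pd.DataFrame:
    rows = []
    for cs in sets:
        for i, count in enumerate(cs.counts, start=1):
            rows.append(
                {
                    "strain_id": cs.strain_id,
                    "reporter": cs.reporter,
                    "culture_id": i,
                    "mutant_count": int(count),
                    "Nt": cs.Nt,
                    "plated_fraction": cs.plated_fraction,
                }
            )
    return pd.DataFrame(rows, columns=CULTURE_COLUMNS)


def write_cultures(sets: list[CultureSet], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cultures_to_frame(sets).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[VariantIncidence]:
    """Read a variant-incidence table, pooling rows per variant."""
    df = _read_tsv(path)
    _require_columns(df, VARIANT_COLUMNS, path)
    for col in ("occurrences", "denominator"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(-1)))
        if bad.any():
            raise ValidationError(
                f"{path}: {col} must be a non-negative integer "
                f"(line {_bad_lines(df, bad.to_numpy())})"
            )
        df[col] = vals.astype(np.int64)
    out = []
    for vid, rows in df.groupby("variant_id", sort=False):
        parts = [
            VariantIncidence(str(vid), int(r.occurrences), int(r.denominator))
            for r in rows.itertuples()
        ]
        out.append(combine_incidence(*parts))
    return out
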