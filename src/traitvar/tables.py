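"""Reading, validating, filtering and summarizing individual trait tables.

The canonical in-memory container is a pandas DataFrame with columns
``individual_id``, ``species``, ``site``, ``plot`` (nullable) and one
column per trait; the on-disk format is plain CSV.  An XLSX sheet with
the same columns can be ingested through the same reader (pandas +
openpyxl), so a deposited spreadsheet of real measurements can be
dropped in unchanged.

All standard deviations use the n-1 denominator.  Species observed only
once get ``sd``/``cv`` reported as NaN (undefined), never 0, and are
excluded from cross-species mean-CV aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TableValidationError
from .simulate import ID_COL, PLOT_COL, SITE_COL, SPECIES_COL

__all__ = [
    "DEFAULT_TRAITS",
    "read_individual_table",
    "write_individual_table",
    "filter_focal_species",
    "species_summaries",
    "mean_cv",
    "trait_correlation",
]

#: Default trait registry: column name -> unit.
DEFAULT_TRAITS: dict[str, str] = {"body_mass_g": "g", "back_leg_length_mm": "mm"}

_MANDATORY = (ID_COL, SPECIES_COL, SITE_COL)


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a row was rejected during validation."""

    row: int
    column: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, column {self.column!r}: {self.reason}"


def _validate(df: pd.DataFrame, traits: Sequence[str]) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    for col in _MANDATORY:
        if col not in df.columns:
            raise TableValidationError(f"missing mandatory column {col!r}")
    missing_traits = [t for t in traits if t not in df.columns]
    if missing_traits:
        raise TableValidationError(f"missing trait column(s) {missing_traits}")
    dup = df[ID_COL][df[ID_COL].duplicated()]
    if len(dup):
        raise TableValidationError(f"duplicate individual_id values: {sorted(set(dup))[:5]}")

    diagnostics: list[RowDiagnostic] = []
    bad = pd.Series(False, index=df.index)
    for t in traits:
        vals = pd.to_numeric(df[t], errors="coerce")
        invalid = vals.isna() | ~np.isfinite(vals) | (vals <= 0)
        for row in df.index[invalid]:
            reason = "missing or non-numeric" if pd.isna(vals[row]) else f"non-positive value {vals[row]!r}"
            diagnostics.append(RowDiagnostic(row=int(row), column=t, reason=reason))
        bad |= invalid
        df[t] = vals
    return df.loc[~bad].reset_index(drop=True), diagnostics


def read_individual_table(
    source: str | Path | pd.DataFrame,
    traits: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
    on_invalid: str = "warn",
) -> pd.DataFrame:
    """Read and validate an individual-level trait table.

    Parameters
    ----------
    source : CSV path, XLSX path, or an already-loaded DataFrame.
    traits : trait column names to validate; default :data:`DEFAULT_TRAITS`.
    column_map : optional ``{source column -> canonical column}`` renaming.
    on_invalid : what to do with rows carrying missing or non-positive
        trait values: ``"warn"`` (drop with a warning listing row and
        column), ``"drop"`` (silently), or ``"raise"``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    trait_list = list(traits) if traits is not None else [t for t in DEFAULT_TRAITS if t in df.columns]
    if not trait_list:
        raise TableValidationError("no trait columns found or specified")
    if PLOT_COL not in df.columns:
        df[PLOT_COL] = pd.Series([pd.NA] * len(df), dtype="string")
    df[PLOT_COL] = df[PLOT_COL].astype("string")

    clean, diagnostics = _validate(df, trait_list)
    if diagnostics:
        msg = "; ".join(str(d) for d in diagnostics[:10])
        if on_invalid == "raise":
            raise TableValidationError(f"invalid rows: {msg}")
        if on_invalid == "warn":
            warnings.warn(f"dropped {len(diagnostics)} invalid value(s): {msg}", stacklevel=2)
    return clean


def write_individual_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV (the native interchange format)."""
    table.to_csv(path, index=False)


def filter_focal_species(table: pd.DataFrame, min_n: int = 50) -> pd.DataFrame:
    """Keep only individuals of species sampled at least ``min_n`` times.

    Mirrors the focal-species rule used to decide which species are
    well enough sampled for variability analyses.  Idempotent; warns
    (does not raise) if no species survives.
    """
    if min_n < 1:
        raise ValueError(f"min_n must be >= 1, got {min_n}")
    counts = table[SPECIES_COL].value_counts()
    keep = counts.index[counts >= min_n]
    out = table[table[SPECIES_COL].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no species has n >= {min_n}; result is empty", stacklevel=2)
    return out


def species_summaries(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-species n, mean, sd, cv, min, max for one trait.

    sd uses the n-1 denominator; cv = sd/mean.  For n = 1 species sd
    and cv are NaN (undefined), not 0.
    """
    if trait not in table.columns:
        raise KeyError(f"unknown trait {trait!r}")
    g = table.groupby(SPECIES_COL, sort=True)[trait]
    out = g.agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1), min="min", max="max").reset_index()
    out.insert(1, "trait", trait)
    out["cv"] = out["sd"] / out["mean"]
    return out[[SPECIES_COL, "trait", "n", "mean", "sd", "cv", "min", "max"]]


def mean_cv(summaries: pd.DataFrame) -> float:
    """Cross-species mean CV, excluding species whose CV is undefined."""
    return float(summaries["cv"].dropna().mean())


def trait_correlation(table: pd.DataFrame, trait_a: str, trait_b: str) -> float:
    """Pearson product-moment correlation of two traits over individuals."""
    for t in (trait_a, trait_b):
        if t not in table.columns:
            raise KeyError(f"unknown trait {t!r}")
    sub = table[[trait_a, trait_b]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 individuals with both traits, got {len(sub)}")
    a = sub[trait_a].to_numpy(float)
    b = sub[trait_b].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a trait has zero variance")
    return float(np.corrcoef(a, b)[0, 1])
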