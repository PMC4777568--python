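"""Single-trait functional diversity indices per plot-community.

Two indices, each computed twice per community:

* CWM (community-weighted mean) — with intraspecific variability it is
  the plain mean over the community's individuals; without, the mean of
  species trait means weighted by species abundances (which is the same
  weighting, applied to means instead of individual values).
* FRic (functional richness) — for a single trait, the range
  (max - min) of the values present: individual values with, species
  means without.

Species means default to "global" means over all individuals of the
species in the whole table (the convention when a trait database or a
full collection supplies one value per species).  With
``species_mean_source="community"`` means are recomputed within each
community, in which case CWM with and without coincide exactly and the
with-variability range can only widen.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import PLOT_COL, SITE_COL, SPECIES_COL

__all__ = [
    "cwm_with_itv",
    "cwm_without_itv",
    "fric_single_trait",
    "fric_percent_increase",
    "community_fd",
]


def cwm_without_itv(abundances: Mapping[str, int], species_means: Mapping[str, float]) -> float:
    """Abundance-weighted mean of species trait means."""
    if not abundances:
        raise ValueError("community has no species")
    tot = w = 0.0
    for sp, a in abundances.items():
        if a <= 0:
            raise ValueError(f"abundance of {sp!r} must be > 0, got {a}")
        if sp not in species_means:
            raise KeyError(f"no trait mean for species {sp!r}")
        tot += a * species_means[sp]
        w += a
    return tot / w


def cwm_with_itv(values) -> float:
    """Mean trait value over a community's individuals."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("community has no individuals")
    return float(arr.mean())


def fric_single_trait(values) -> float:
    """Single-trait functional richness: the range max - min (0 for one value)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("functional richness undefined for an empty community")
    return float(arr.max() - arr.min())


def fric_percent_increase(fric_individuals: float, fric_species_means: float) -> float:
    """Percent widening of the trait range when individuals replace species means."""
    if fric_species_means <= 0:
        raise ValueError("species-mean FRic must be > 0 to express an increase")
    return (fric_individuals - fric_species_means) / fric_species_means * 100.0


def community_fd(
    table: pd.DataFrame,
    trait: str,
    species_means: Mapping[str, float] | pd.Series | None = None,
    species_mean_source: str = "global",
) -> pd.DataFrame:
    """CWM and FRic per plot, each with and without intraspecific variability.

    Parameters
    ----------
    table : individual table; rows without a plot label are used for
        global species means but belong to no community.
    species_means : optional explicit per-species means; otherwise
        derived according to ``species_mean_source``.
    species_mean_source : ``"global"`` (default; means over every
        individual of the species in the table) or ``"community"``
        (means recomputed within each plot).

    Returns one row per plot: plot, site, n_species, n_individuals,
    cwm_with_itv, cwm_without_itv, fric_with_itv, fric_without_itv.
    """
    if trait not in table.columns:
        raise KeyError(f"unknown trait {trait!r}")
    if species_mean_source not in ("global", "community"):
        raise ValueError(f"species_mean_source must be 'global' or 'community', got {species_mean_source!r}")
    if species_means is None and species_mean_source == "global":
        species_means = table.groupby(SPECIES_COL)[trait].mean()
    if species_means is not None:
        species_means = dict(pd.Series(species_means))

    members = table[table[PLOT_COL].notna()]
    rows = []
    for plot, sub in members.groupby(PLOT_COL, sort=True):
        values = sub[trait].to_numpy(float)
        if species_mean_source == "community" and species_means is None:
            means_here = sub.groupby(SPECIES_COL)[trait].mean().to_dict()
        else:
            means_here = species_means
        abund = sub[SPECIES_COL].value_counts().to_dict()
        mean_vals = np.array([means_here[sp] for sp in abund])
        rows.append(
            {
                "plot": plot,
                "site": sub[SITE_COL].iloc[0],
                "trait": trait,
                "n_species": len(abund),
                "n_individuals": len(sub),
                "cwm_with_itv": cwm_with_itv(values),
                "cwm_without_itv": cwm_without_itv(abund, means_here),
                "fric_with_itv": fric_single_trait(values),
                "fric_without_itv": fric_single_trait(mean_vals),
            }
        )
    return pd.DataFrame(rows)
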