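"""Bootstrap determination of the minimum adequate sample size per trait.

For a species' measured trait values, subsets of size k are drawn with
replacement (n_boot per size); each subset's standard error is
sd(subset, ddof=1)/sqrt(k), and the n_boot SEs are averaged into a mean
SE for that size.  The minimum adequate sample size is the smallest
size on the grid whose mean SE falls within a fraction (default 5%) of
the reference mean — the mean over every individual in scope.  A
single-site variant restricts both the resampling pool and the
reference mean to the site where the species is most abundant.

The default size grid is {3, 5, 10, 15, ..., 100}, truncated at the
number of individuals available.  Each size uses a fresh RNG substream
derived from (seed, k), so extending the grid never changes earlier
values and curves are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SITE_COL, SPECIES_COL

__all__ = [
    "default_grid",
    "bootstrap_mean_se",
    "min_sample_size",
    "site_restricted_curve",
    "curves_for_table",
    "ResamplingCurve",
]


def default_grid(max_size: int = 100) -> list[int]:
    """Subset sizes {3, 5, 10, ..., max_size}."""
    return [3] + list(range(5, max_size + 1, 5))


@dataclass(frozen=True)
class ResamplingCurve:
    """Mean bootstrap SE across subset sizes for one species x trait x scope."""

    species: str | None
    trait: str | None
    scope: str
    grid: tuple[int, ...]
    mean_se: tuple[float, ...]
    mc_se: tuple[float, ...]  # Monte-Carlo sd of each mean_se estimate
    reference_mean: float
    threshold_fraction: float
    n_boot: int
    seed: int
    min_adequate_n: int | None
    site: str | None = None
    site_tie: bool = False

    @property
    def threshold(self) -> float:
        return self.threshold_fraction * self.reference_mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "trait": self.trait,
                "scope": self.scope,
                "k": list(self.grid),
                "mean_se": list(self.mean_se),
                "threshold": self.threshold,
                "min_adequate_n": self.min_adequate_n,
            }
        )


def bootstrap_mean_se(
    values: np.ndarray,
    k: int,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean over n_boot resamples of size k of sd(sample, ddof=1)/sqrt(k)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if k < 2:
        raise ValueError(f"subset size must be >= 2 (SE undefined), got {k}")
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    samples = rng.choice(values, size=(n_boot, k), replace=True)
    ses = samples.std(axis=1, ddof=1) / np.sqrt(k)
    return float(ses.mean())


def min_sample_size(
    values: np.ndarray,
    grid: list[int] | None = None,
    threshold_fraction: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    species: str | None = None,
    trait: str | None = None,
    scope: str = "all_sites",
    site: str | None = None,
    site_tie: bool = False,
) -> ResamplingCurve:
    """Fill a resampling curve and locate the minimum adequate sample size.

    Grid sizes larger than the number of available individuals are
    dropped (resampling stops at the species' sample size).  If no grid
    size reaches the threshold, ``min_adequate_n`` is None.
    """
    values = np.asarray(values, dtype=float)
    grid = default_grid() if grid is None else sorted(set(int(k) for k in grid))
    grid = [k for k in grid if 2 <= k <= values.size]
    if not grid:
        raise ValueError("no feasible subset size: grid empty after truncation")
    ref_mean = float(values.mean())

    mean_ses: list[float] = []
    mc_ses: list[float] = []
    for k in grid:
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        samples = rng.choice(values, size=(n_boot, k), replace=True)
        ses = samples.std(axis=1, ddof=1) / np.sqrt(k)
        mean_ses.append(float(ses.mean()))
        mc_ses.append(float(ses.std(ddof=1) / np.sqrt(n_boot)) if n_boot > 1 else 0.0)

    threshold = threshold_fraction * ref_mean
    min_n = next((k for k, se in zip(grid, mean_ses) if se <= threshold), None)
    return ResamplingCurve(
        species=species,
        trait=trait,
        scope=scope,
        grid=tuple(grid),
        mean_se=tuple(mean_ses),
        mc_se=tuple(mc_ses),
        reference_mean=ref_mean,
        threshold_fraction=threshold_fraction,
        n_boot=n_boot,
        seed=seed,
        min_adequate_n=min_n,
        site=site,
        site_tie=site_tie,
    )


def site_restricted_curve(
    table: pd.DataFrame,
    species: str,
    trait: str,
    grid: list[int] | None = None,
    threshold_fraction: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> ResamplingCurve:
    """Resampling curve using only the species' most-abundant site.

    Both the resampling pool and the reference mean come from that one
    site.  Abundance ties are broken towards the lexicographically
    lowest site label and flagged on the curve.
    """
    sub = table[table[SPECIES_COL] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} not present in table")
    counts = sub.groupby(SITE_COL).size().sort_index()
    best = counts.idxmax()  # first (lowest label) among ties
    tie = int((counts == counts.max()).sum()) > 1
    values = sub.loc[sub[SITE_COL] == best, trait].to_numpy(float)
    return min_sample_size(
        values,
        grid=grid,
        threshold_fraction=threshold_fraction,
        n_boot=n_boot,
        seed=seed,
        species=species,
        trait=trait,
        scope=f"single_site({best})",
        site=str(best),
        site_tie=tie,
    )


def curves_for_table(
    table: pd.DataFrame,
    trait: str,
    scope: str = "all_sites",
    grid: list[int] | None = None,
    threshold_fraction: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[ResamplingCurve]:
    """One resampling curve per species in the table, pooled or single-site."""
    curves = []
    for sp, sub in table.groupby(SPECIES_COL, sort=True):
        if scope == "all_sites":
            curves.append(
                min_sample_size(
                    sub[trait].to_numpy(float),
                    grid=grid,
                    threshold_fraction=threshold_fraction,
                    n_boot=n_boot,
                    seed=seed,
                    species=str(sp),
                    trait=trait,
                )
            )
        elif scope == "single_site":
            curves.append(
                site_restricted_curve(
                    table, str(sp), trait, grid=grid,
                    threshold_fraction=threshold_fraction, n_boot=n_boot, seed=seed,
                )
            )
        else:
            raise ValueError(f"scope must be 'all_sites' or 'single_site', got {scope!r}")
    return curves
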