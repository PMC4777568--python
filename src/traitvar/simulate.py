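"""Synthetic individual-level trait tables and plot-communities.

``generate_individuals`` draws a species pool with log-normal species
means, distributes each species' individuals across sites, and adds
unit-mean log-normal intraspecific noise.  ``assign_communities``
partitions the individuals of each site into plot-communities with
controlled richness and abundance.  Both are deterministic given the
config seed: each stage uses its own ``SeedSequence([seed, stage])``
stream, so adding a stage never perturbs an earlier one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .errors import GenerationError

__all__ = ["generate_individuals", "assign_communities", "generate_dataset", "species_mean_table"]

# schema of the individual table
ID_COL = "individual_id"
SPECIES_COL = "species"
SITE_COL = "site"
PLOT_COL = "plot"

_STAGE_INDIVIDUALS = 0
_STAGE_COMMUNITIES = 1


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def species_mean_table(config: SyntheticConfig) -> pd.DataFrame:
    """True species-mean trait values implied by the config and seed.

    Returns one row per species with a column per trait.  The same
    draws are used inside :func:`generate_individuals`, so this is the
    generator's ground truth for tests and calibration checks.
    """
    config.validate()
    rng = _rng(config, _STAGE_INDIVIDUALS)
    return _draw_species_means(config, rng)


def _draw_species_means(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    k = config.n_species
    names = [f"sp{i + 1:02d}" for i in range(k)]
    log_means: dict[str, np.ndarray] = {}
    for t in config.traits:
        if t.allometric_on is None:
            log_means[t.name] = rng.normal(t.log10_mean, t.log10_sd, size=k)
        else:
            base = log_means[t.allometric_on]
            resid = rng.normal(0.0, t.log10_residual_sd, size=k)
            log_means[t.name] = t.allometric_intercept + t.allometric_slope * base + resid
    out = pd.DataFrame({SPECIES_COL: names})
    for t in config.traits:
        out[t.name] = 10.0 ** log_means[t.name]
    return out


def generate_individuals(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one row per individual: id, species, site, plot (empty), traits.

    Each individual's trait value is

        species mean  x  10^(site shift)  x  exp(s*z - s^2/2),

    with ``s^2 = ln(1 + CV^2)`` so the multiplier has unit mean and the
    realized linear-scale CV matches the configured CV in expectation.
    The first ``n_focal`` species receive abundances in
    ``focal_abundance_range``; the rest are capped below ``focal_min_n``
    so the focal set is exactly the configured size.
    """
    config.validate()
    rng = _rng(config, _STAGE_INDIVIDUALS)
    means = _draw_species_means(config, rng)

    lo, hi = config.abundance_range
    hi = min(hi, config.focal_min_n - 1)
    lo = min(lo, hi)
    flo, fhi = config.focal_abundance_range
    counts = np.concatenate(
        [
            rng.integers(flo, fhi + 1, size=config.n_focal),
            rng.integers(lo, hi + 1, size=config.n_species - config.n_focal),
        ]
    )
    # per-species site preferences: Dirichlet so "greatest abundance" sites vary
    site_probs = rng.dirichlet(np.ones(config.n_sites), size=config.n_species)
    site_shift = rng.normal(0.0, config.site_effect_sd, size=(config.n_species, config.n_sites))
    if config.site_effect_sd == 0.0:
        site_shift[:] = 0.0

    sites = [f"site{j + 1}" for j in range(config.n_sites)]
    rows: list[pd.DataFrame] = []
    for i, sp in enumerate(means[SPECIES_COL]):
        n = int(counts[i])
        site_idx = rng.choice(config.n_sites, size=n, p=site_probs[i])
        block = pd.DataFrame(
            {
                ID_COL: [f"{sp}-{j + 1:04d}" for j in range(n)],
                SPECIES_COL: sp,
                SITE_COL: [sites[j] for j in site_idx],
                PLOT_COL: pd.Series([pd.NA] * n, dtype="string"),
            }
        )
        for t in config.traits:
            mean_i = float(means.loc[i, t.name])
            s = np.sqrt(np.log1p(t.cv**2))
            noise = np.exp(s * rng.standard_normal(n) - 0.5 * s**2) if t.cv > 0 else np.ones(n)
            block[t.name] = mean_i * 10.0 ** site_shift[i, site_idx] * noise
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)
    return table


def assign_communities(table: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Partition each site's individuals into plot-communities.

    For every plot: draw a richness within the configured range (capped
    by the species still available at the site), pick that many species
    with probability proportional to their unassigned abundance, seed
    the plot with one individual of each, then fill towards a
    right-skewed (clipped log-normal) target abundance from the chosen
    species' remaining pools, reserving enough individuals for the
    site's remaining plots.  Each individual ends up in at most one
    plot; realized richness and abundance always fall inside the
    configured ranges.

    Raises
    ------
    GenerationError
        If a site runs out of unassigned individuals before all its
        plots receive the minimum richness.
    """
    config.validate()
    rng = _rng(config, _STAGE_COMMUNITIES)
    rmin, rmax = config.plot_richness_range
    amin, amax = config.plot_abundance_range

    out = table.copy()
    out[PLOT_COL] = pd.Series([pd.NA] * len(out), dtype="string")
    for site in sorted(out[SITE_COL].unique()):
        site_rows = out.index[out[SITE_COL] == site]
        # unassigned individual row-indices per species, in stable order
        pools: dict[str, list[int]] = {
            sp: list(idx)
            for sp, idx in out.loc[site_rows].groupby(SPECIES_COL, sort=True).groups.items()
        }
        for p in range(config.n_plots_per_site):
            plot_id = f"{site}-p{p + 1:02d}"
            avail = [sp for sp, idx in pools.items() if idx]
            if len(avail) < rmin:
                raise GenerationError(
                    f"site {site}: only {len(avail)} species left unassigned, "
                    f"cannot reach plot richness >= {rmin} for {plot_id}"
                )
            r = int(rng.integers(rmin, min(rmax, len(avail)) + 1))
            weights = np.array([len(pools[sp]) for sp in avail], dtype=float)
            chosen = rng.choice(avail, size=r, replace=False, p=weights / weights.sum())
            # reserve rmin individuals for each remaining plot at this site
            pool_left = int(sum(len(idx) for idx in pools.values()))
            plots_after = config.n_plots_per_site - p - 1
            cap = min(amax, pool_left - plots_after * rmin)
            mu, sd = config.plot_abundance_lognormal
            draw = int(np.round(rng.lognormal(mu, sd))) if sd > 0 else int(np.round(np.exp(mu)))
            target = int(np.clip(draw, max(amin, r), max(max(amin, r), cap)))
            members: list[int] = []
            for sp in chosen:
                pool = pools[sp]
                j = int(rng.integers(len(pool)))
                members.append(pool.pop(j))
            extra_pool = [i for sp in chosen for i in pools[sp]]
            n_extra = min(target - r, len(extra_pool))
            if n_extra > 0:
                extras = rng.choice(len(extra_pool), size=n_extra, replace=False)
                taken = {extra_pool[int(e)] for e in extras}
                members.extend(sorted(taken))
                for sp in chosen:
                    pools[sp] = [i for i in pools[sp] if i not in taken]
            out.loc[members, PLOT_COL] = plot_id
    return out


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Convenience: generate individuals and assign plot-communities."""
    return assign_communities(generate_individuals(config), config)
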