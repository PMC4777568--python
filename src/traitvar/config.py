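"""Configuration for the synthetic individual-trait generator.

The generator emulates the structure of a field dataset of dung-beetle
morphology: ~60 species sampled across three forest sites, a subset of
"focal" species with at least 50 measured individuals each, and 90
baited experimental plots whose captured beetles form small naturally
assembled communities (1-11 species, 1-95 individuals).

Two traits ship by default:

* dry body mass (g) — species means log-normal across species, high
  intraspecific variability (CV 0.33);
* back leg length (mm) — tied to body mass through an allometric power
  law on the log10 scale, low intraspecific variability (CV 0.10).

Species-mean spreads are calibrated so that 13 focal species span
roughly 0.005-0.804 g and 2.32-15.59 mm, and so that between-species
differences carry ~95% of log10-scale trait variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError

__all__ = ["TraitModel", "SyntheticConfig", "load_config"]


@dataclass(frozen=True)
class TraitModel:
    """Generating model for one trait.

    A trait either has its own log-normal distribution of species means
    (``log10_mean``/``log10_sd``) or is allometrically coupled to
    another trait: ``log10(mean) = intercept + slope * log10(base mean)
    + N(0, residual_sd)``.

    ``cv`` is the intraspecific coefficient of variation on the linear
    scale; individual values are species mean times a unit-mean
    log-normal multiplier with that CV.
    """

    name: str
    unit: str
    cv: float
    log10_mean: float | None = None
    log10_sd: float | None = None
    allometric_on: str | None = None
    allometric_slope: float = 0.0
    allometric_intercept: float = 0.0
    log10_residual_sd: float = 0.0

    def validate(self) -> None:
        if not self.name:
            raise ConfigurationError("trait name must be non-empty")
        if self.cv < 0:
            raise ConfigurationError(f"trait {self.name!r}: cv must be >= 0, got {self.cv}")
        own = self.log10_mean is not None and self.log10_sd is not None
        if own and self.log10_sd < 0:
            raise ConfigurationError(f"trait {self.name!r}: log10_sd must be >= 0")
        if not own and self.allometric_on is None:
            raise ConfigurationError(
                f"trait {self.name!r}: needs either (log10_mean, log10_sd) or allometric_on"
            )
        if self.allometric_on is not None and self.log10_residual_sd < 0:
            raise ConfigurationError(f"trait {self.name!r}: log10_residual_sd must be >= 0")


#: Body mass: species-mean log10 sd 0.60 puts ~95% of log10 variance between
#: species at CV 0.33 and spans ~2 decades across 13 focal species.
BODY_MASS = TraitModel(
    name="body_mass_g", unit="g", cv=0.33, log10_mean=-1.20, log10_sd=0.60
)

#: Back leg length: allometric slope ~0.38 maps the 2-decade mass span onto
#: ~0.8 decades of leg length (2.3-15.6 mm), as observed for scarab legs.
BACK_LEG = TraitModel(
    name="back_leg_length_mm",
    unit="mm",
    cv=0.10,
    allometric_on="body_mass_g",
    allometric_slope=0.376,
    allometric_intercept=1.23,
    log10_residual_sd=0.05,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic dataset.

    Parameters
    ----------
    n_species : total number of species in the pool.
    n_focal : number of species forced to have >= ``focal_min_n``
        individuals (the well-sampled species all analyses focus on).
    focal_min_n : threshold defining a focal species.
    abundance_range : inclusive total-abundance range for non-focal
        species; the upper end is additionally capped at
        ``focal_min_n - 1`` so the focal set is exactly ``n_focal``.
    focal_abundance_range : inclusive total-abundance range for focal
        species.
    n_sites, n_plots_per_site : sampling design (3 sites x 30 plots).
    plot_richness_range, plot_abundance_range : inclusive bounds every
        assembled plot-community must respect.
    site_effect_sd : sd of a per species-by-site multiplicative shift on
        the log10 scale; 0 (the default) makes the generating model the
        exact two-level hierarchy assumed by variance partitioning.
    traits : generating models, in dependency order.
    seed : master seed; every stage derives its own stream from it.
    """

    n_species: int = 61
    n_focal: int = 13
    focal_min_n: int = 50
    abundance_range: tuple[int, int] = (1, 239)
    focal_abundance_range: tuple[int, int] = (51, 229)
    n_sites: int = 3
    n_plots_per_site: int = 30
    plot_richness_range: tuple[int, int] = (1, 11)
    plot_abundance_range: tuple[int, int] = (1, 95)
    #: ln-scale (mean, sd) of the right-skewed plot-abundance targets,
    #: clipped into plot_abundance_range; median ~18, mean ~25 individuals
    #: per plot, emulating capture counts of ~22 on average with rare large
    #: plots near the upper bound.
    plot_abundance_lognormal: tuple[float, float] = (2.9, 0.8)
    site_effect_sd: float = 0.0
    traits: tuple[TraitModel, ...] = (BODY_MASS, BACK_LEG)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_species", "n_focal", "focal_min_n", "n_sites", "n_plots_per_site"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_focal > self.n_species:
            raise ConfigurationError("n_focal cannot exceed n_species")
        for name in (
            "abundance_range",
            "focal_abundance_range",
            "plot_richness_range",
            "plot_abundance_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} must satisfy 1 <= min <= max, got {(lo, hi)}")
        if self.focal_abundance_range[0] < self.focal_min_n:
            raise ConfigurationError("focal_abundance_range min must be >= focal_min_n")
        if self.site_effect_sd < 0:
            raise ConfigurationError("site_effect_sd must be >= 0")
        if self.plot_abundance_lognormal[1] < 0:
            raise ConfigurationError("plot_abundance_lognormal sd must be >= 0")
        if not self.traits:
            raise ConfigurationError("traits must be non-empty")
        seen: set[str] = set()
        for t in self.traits:
            t.validate()
            if t.name in seen:
                raise ConfigurationError(f"duplicate trait {t.name!r}")
            if t.allometric_on is not None and t.allometric_on not in seen:
                raise ConfigurationError(
                    f"trait {t.name!r}: allometric_on {t.allometric_on!r} must precede it"
                )
            seen.add(t.name)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _trait_from_mapping(d: dict) -> TraitModel:
    return TraitModel(**d)


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a :class:`SyntheticConfig` from a YAML mapping.

    Keys mirror the dataclass fields; ``traits`` is a list of mappings.
    Omitted keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    kwargs = dict(raw)
    if "traits" in kwargs:
        kwargs["traits"] = tuple(_trait_from_mapping(t) for t in kwargs["traits"])
    for key in ("abundance_range", "focal_abundance_range", "plot_richness_range", "plot_abundance_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        cfg = SyntheticConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.validate()
    return cfg
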