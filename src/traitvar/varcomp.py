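"""One-way random-effects variance partitioning of log10 traits.

The model is the classic two-level hierarchy

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma2_between),
                              e_ij ~ N(0, sigma2_within),

with species as the single random grouping factor and individuals as
residual replication, fitted to log10-transformed trait values.  Two
estimators are provided:

* ``anova`` — the unbalanced method-of-moments (expected mean squares)
  estimator: sigma2_within = MSW, sigma2_between = (MSB - MSW)/n0 with
  n0 = (N - sum n_i^2 / N)/(k - 1); negative between-species estimates
  are truncated at 0 and flagged.
* ``reml`` — restricted maximum likelihood, obtained by profiling out
  the grand mean and the residual variance and optimizing the single
  remaining parameter, the variance ratio lambda = sigma2_b/sigma2_w.
  On balanced designs with an interior solution REML and ANOVA agree
  exactly.

Percentage shares are component / (between + within) x 100 and sum to
100 whenever total variance is positive; for a degenerate table with
zero total variance they are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import EstimationError
from .simulate import SPECIES_COL

__all__ = [
    "VarianceComponents",
    "log10_transform",
    "anova_variance_components",
    "reml_variance_components",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Between/within-species variance estimates for one trait (log10 scale)."""

    trait: str
    sigma2_between: float
    sigma2_within: float
    pct_between: float
    pct_within: float
    estimator: str
    n_species: int
    n_individuals: int
    converged: bool = True
    truncated: bool = False

    def __post_init__(self) -> None:
        total = self.sigma2_between + self.sigma2_within
        if total > 0:
            s = self.pct_between + self.pct_within
            assert abs(s - 100.0) < 1e-9, f"shares sum to {s}"


def log10_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Elementwise base-10 log; rejects non-positive values by position."""
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0) | ~np.isfinite(arr))[0]
    if bad.size:
        raise ValueError(
            f"log10 undefined for non-positive value {arr[bad[0]]!r} at position {bad[0]}"
        )
    return np.log10(arr)


def _grouped(table: pd.DataFrame, trait: str, log10: bool) -> list[np.ndarray]:
    if trait not in table.columns:
        raise KeyError(f"unknown trait {trait!r}")
    groups = [
        np.asarray(v, dtype=float)
        for _, v in table.groupby(SPECIES_COL, sort=True)[trait]
    ]
    if len(groups) < 2:
        raise EstimationError("need >= 2 species to partition variance")
    if max(len(g) for g in groups) < 2:
        raise EstimationError("all species are singletons: within-species variance undefined")
    if log10:
        groups = [log10_transform(g) for g in groups]
    return groups


def _components(trait, s2b, s2w, estimator, k, n, converged=True, truncated=False):
    total = s2b + s2w
    if total > 0:
        pct_b = 100.0 * s2b / total
        pct_w = 100.0 - pct_b
    else:
        pct_b = pct_w = float("nan")
    return VarianceComponents(
        trait=trait,
        sigma2_between=s2b,
        sigma2_within=s2w,
        pct_between=pct_b,
        pct_within=pct_w,
        estimator=estimator,
        n_species=k,
        n_individuals=n,
        converged=converged,
        truncated=truncated,
    )


def anova_variance_components(
    table: pd.DataFrame, trait: str, log10: bool = True
) -> VarianceComponents:
    """Method-of-moments estimator for the one-way random-effects model.

    Set ``log10=False`` to analyse values already on the modelling scale.
    """
    groups = _grouped(table, trait, log10)
    n_i = np.array([len(g) for g in groups], dtype=float)
    k, n = len(groups), int(n_i.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()

    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = float((n_i * (means - grand) ** 2).sum())
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - (n_i**2).sum() / n) / (k - 1)
    s2b = (msb - msw) / n0
    truncated = s2b < 0
    return _components(trait, max(s2b, 0.0), msw, "anova_mom", k, n, truncated=truncated)


def _reml_neg2_profile(lam: float, groups: list[np.ndarray]) -> float:
    """-2 x restricted log-likelihood profiled over mu and sigma2_within.

    With V_i = sigma2_w (I + lambda J), w_i = n_i/(1 + n_i lambda):
      Q(lambda) = sum_i [SSW_i + w_i (ybar_i - muhat)^2],
      sigma2_w-hat = Q/(N-1), and (dropping constants)
      -2 l_R = (N-1) ln Q + sum_i ln(1 + n_i lambda) + ln(sum_i w_i).
    """
    n_i = np.array([len(g) for g in groups], dtype=float)
    ybar = np.array([g.mean() for g in groups])
    ssw = np.array([((g - g.mean()) ** 2).sum() for g in groups])
    w = n_i / (1.0 + n_i * lam)
    mu = (w * ybar).sum() / w.sum()
    q = float(ssw.sum() + (w * (ybar - mu) ** 2).sum())
    n = n_i.sum()
    return (n - 1) * np.log(q) + np.log1p(n_i * lam).sum() + np.log(w.sum())


def reml_variance_components(
    table: pd.DataFrame, trait: str, log10: bool = True, lam_max: float = 1e7
) -> VarianceComponents:
    """REML estimator for the one-way random-effects model.

    The restricted likelihood is maximized over the variance ratio
    lambda = sigma2_between/sigma2_within on a log grid plus a bounded
    Brent refinement; lambda = 0 (boundary) is always evaluated, so a
    dataset with no between-species signal lands exactly on the
    boundary with ``converged=True``.
    """
    groups = _grouped(table, trait, log10)
    n_i = np.array([len(g) for g in groups], dtype=float)
    k, n = len(groups), int(n_i.sum())
    if np.ptp(np.concatenate(groups)) == 0.0:
        return _components(trait, 0.0, 0.0, "reml", k, n)

    obj = lambda lam: _reml_neg2_profile(lam, groups)
    # coarse bracket on a log grid, then local refinement
    grid = np.concatenate([[0.0], np.logspace(-8, np.log10(lam_max), 120)])
    vals = np.array([obj(l) for l in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    converged = True
    if j == 0:
        lam_hat = 0.0
        # confirm the boundary beats the best interior neighbour
        res = minimize_scalar(obj, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-12})
        if res.fun < obj(0.0) - 1e-10:
            lam_hat = float(res.x)
    else:
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
        converged = bool(res.success)
        if not converged:
            raise EstimationError(f"REML optimizer failed near lambda={res.x!r}")
        lam_hat = float(res.x)

    q = _reml_q(lam_hat, groups)
    s2w = q / (n - 1)
    s2b = lam_hat * s2w
    return _components(trait, s2b, s2w, "reml", k, n, converged=converged)


def _reml_q(lam: float, groups: list[np.ndarray]) -> float:
    n_i = np.array([len(g) for g in groups], dtype=float)
    ybar = np.array([g.mean() for g in groups])
    ssw = np.array([((g - g.mean()) ** 2).sum() for g in groups])
    w = n_i / (1.0 + n_i * lam)
    mu = (w * ybar).sum() / w.sum()
    return float(ssw.sum() + (w * (ybar - mu) ** 2).sum())
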