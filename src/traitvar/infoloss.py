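"""Information lost by computing functional diversity from species means.

Across communities, index values computed without intraspecific
variability (species means) are regressed on values computed with it
(individual measurements): y = a + b x by ordinary least squares, with
the with-variability values on the x axis.  R-squared measures how much
of the among-community variation in the full-information index survives
the species-mean shortcut, so

    info_loss_pct = (1 - R^2) * 100

is the percentage of information excluded by omitting intraspecific
variability.  For simple linear regression R^2 is the squared Pearson
correlation of the two series, hence orientation-invariant; the
orientation only affects the reported slope and intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError

__all__ = ["InfoLossResult", "ols_fit", "itv_information_loss"]


@dataclass(frozen=True)
class InfoLossResult:
    index: str
    trait: str | None
    n_communities: int
    n_excluded: int
    slope: float
    intercept: float
    r2: float
    info_loss_pct: float


def ols_fit(x, y, index: str = "", trait: str | None = None, n_excluded: int = 0) -> InfoLossResult:
    """OLS of without-ITV values (y) on with-ITV values (x).

    Degenerate cases: fewer than 3 pairs or zero variance in x raise;
    zero variance in y (a flat without-ITV series) leaves R^2 and the
    loss undefined (NaN) rather than forcing them to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise EstimationError(f"need >= 3 paired values, got {x.size}")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate fit: zero variance in with-ITV values")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        r2 = float("nan")
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return InfoLossResult(
        index=index,
        trait=trait,
        n_communities=int(x.size),
        n_excluded=n_excluded,
        slope=slope,
        intercept=intercept,
        r2=r2,
        info_loss_pct=(1.0 - r2) * 100.0,
    )


def itv_information_loss(fd: pd.DataFrame, index: str, trait: str | None = None) -> InfoLossResult:
    """Information loss for one index over a ``community_fd`` table.

    ``index`` is ``"cwm"`` or ``"fric"``.  Communities where either
    variant is undefined (NaN) are dropped pairwise; the exclusion
    count is reported on the result.
    """
    index = index.lower()
    if index not in ("cwm", "fric"):
        raise ValueError(f"index must be 'cwm' or 'fric', got {index!r}")
    cols = [f"{index}_with_itv", f"{index}_without_itv"]
    for c in cols:
        if c not in fd.columns:
            raise KeyError(f"column {c!r} missing from FD table")
    sub = fd
    if trait is not None and "trait" in fd.columns:
        sub = fd[fd["trait"] == trait]
        if sub.empty:
            raise ValueError(f"no FD rows for trait {trait!r}")
    pairs = sub[cols].dropna()
    return ols_fit(
        pairs[cols[0]], pairs[cols[1]],
        index=index, trait=trait, n_excluded=len(sub) - len(pairs),
    )
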