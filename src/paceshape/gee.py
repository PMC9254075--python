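"""Marginal model of daily reproduction probability versus age.

Daily reproduction scores within a frond are serially correlated (a frond
that reproduced yesterday may be less likely to reproduce today), so the
age trend in the probability of reproducing is estimated with generalized
estimating equations: a binomial-logit marginal model
``logit P(y = 1 | age) = beta0 + beta1 * age`` with each frond as a
cluster, an AR(1) working correlation across its ordered observation days
(exchangeable and independence structures are available as options), and a
robust sandwich covariance for the coefficients.

Because all species show low reproductive output in their first days, the
first ``omit_first_days`` age-days (default 2) are dropped before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, EmptySelectionError

logger = logging.getLogger(__name__)

CorStr = Literal["ar1", "exchangeable", "independence"]


@dataclass
class GEEDataset:
    """Clustered binary daily-reproduction observations for one species.

    ``frame`` has columns ``frond_id, age, y`` with ages strictly
    increasing within each frond; ``y = 1`` iff the frond produced at
    least one daughter that day (two-daughter days binarize to 1).
    """

    frame: pd.DataFrame
    species: str
    omit_first_days: int

    @property
    def n_clusters(self) -> int:
        return self.frame["frond_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.frame)


def build_gee_dataset(
    cohort: Cohort, species: str, omit_first_days: int = 2
) -> GEEDataset:
    """Assemble per-frond daily reproduction scores for one species.

    One cluster per included frond, observations at ages
    ``omit_first_days + 1 .. death_age``; fronds whose whole life falls
    inside the omitted window are dropped with a logged count.
    """
    fronds = cohort.included(species=species)
    if not fronds:
        raise EmptySelectionError(f"species {species!r} has no included fronds")
    rows = []
    n_dropped = 0
    for f in fronds:
        if f.death_age <= omit_first_days:
            n_dropped += 1
            continue
        for a in range(omit_first_days + 1, f.death_age + 1):
            rows.append((f.frond_id, a, int(f.daily_offspring[a - 1] >= 1)))
    if n_dropped:
        logger.info(
            "species %s: dropped %d frond(s) with death_age <= %d",
            species,
            n_dropped,
            omit_first_days,
        )
    frame = pd.DataFrame(rows, columns=["frond_id", "age", "y"])
    return GEEDataset(frame=frame, species=species, omit_first_days=omit_first_days)


@dataclass
class GEEFit:
    """Fitted marginal reproduction model."""

    beta: np.ndarray  # (intercept, age slope), logit scale
    robust_cov: np.ndarray  # 2x2 sandwich covariance
    alpha: float  # working-correlation parameter (0 for independence)
    phi: float  # dispersion
    corstr: str
    n_clusters: int
    n_obs: int
    converged: bool

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))


_COV_STRUCTS = {
    "ar1": lambda: sm.cov_struct.Autoregressive(grid=True),
    "exchangeable": sm.cov_struct.Exchangeable,
    "independence": sm.cov_struct.Independence,
}


def fit_gee(data: GEEDataset, corstr: CorStr = "ar1") -> GEEFit:
    """Fit the binomial-logit GEE for one species.

    With the independence structure the point estimates coincide with
    ordinary logistic regression; AR(1) lets the working correlation decay
    geometrically over a cluster's consecutive observation days.
    """
    if data.n_clusters < 2:
        raise ValueError("GEE needs at least 2 clusters")
    if data.n_obs < 3:
        raise ValueError("GEE needs at least 3 observations")
    if corstr not in _COV_STRUCTS:
        raise ValueError(f"unknown correlation structure {corstr!r}")
    df = data.frame
    exog = sm.add_constant(df["age"].to_numpy(dtype=float))
    model = sm.GEE(
        df["y"].to_numpy(dtype=float),
        exog,
        groups=df["frond_id"].to_numpy(),
        time=df["age"].to_numpy(dtype=float)[:, None],
        family=sm.families.Binomial(),
        cov_struct=_COV_STRUCTS[corstr](),
    )
    res = model.fit(maxiter=100, ctol=1e-8)
    if corstr == "ar1":
        alpha = float(np.atleast_1d(res.cov_struct.dep_params)[0])
    elif corstr == "exchangeable":
        alpha = float(res.cov_struct.dep_params)
    else:
        alpha = 0.0
    return GEEFit(
        beta=np.asarray(res.params, dtype=float),
        robust_cov=np.asarray(res.cov_params(), dtype=float),
        alpha=alpha,
        phi=float(res.scale),
        corstr=corstr,
        n_clusters=data.n_clusters,
        n_obs=data.n_obs,
        converged=bool(getattr(res, "converged", True)),
    )


def predict_probability(fit: GEEFit, age) -> np.ndarray | float:
    """Marginal reproduction probability at given age(s): expit(b0 + b1*age)."""
    if not fit.converged:
        raise RuntimeError(
            "refusing to predict from a non-converged GEE fit; refit with "
            "more iterations or a simpler correlation structure"
        )
    age_arr = np.asarray(age, dtype=float)
    eta = fit.beta[0] + fit.beta[1] * age_arr
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.isscalar(age) or age_arr.ndim == 0 else p
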