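"""Pace and shape statistics for mortality and fecundity trajectories.

Pace is the absolute time scale of a life history — here the mean
reproductive lifespan of a cohort.  Shape is the time-standardized form of
a trajectory, decoupled from pace:

* ``shape_mortality = 1 - CV`` of lifespan (SD/mean, n-1 denominator).
  Zero under constant hazard (CV of an exponential is 1), approaching one
  when all individuals die at the same age, negative when mortality
  declines with age.  It is a cohort-level quantity — an individual dies
  only once — so it is computed per species-block cell.
* ``shape_fecundity`` is an individual-level OLS slope of mean-standardized
  fecundity (daily count divided by the frond's lifetime mean daily count)
  against pace-standardized age (age divided by the mean lifespan of the
  frond's species-block cell), over the window from first to last
  reproduction.  Negative slopes indicate reproductive senescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, EmptySelectionError, ExclusionError, FrondRecord, lifespans, total_offspring

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


def shape_mortality(values: Sequence[float]) -> float:
    """1 - CV of lifespan for one cohort (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            "shape_mortality needs >= 2 lifespans (SD is undefined for one)"
        )
    mean = x.mean()
    if mean <= 0:
        raise InsufficientDataError("shape_mortality needs a positive mean lifespan")
    return float(1.0 - x.std(ddof=1) / mean)


def pace_shape_table(cohort: Cohort) -> pd.DataFrame:
    """Per-cell and species-pooled pace/shape summary.

    One row per non-empty (species, block) cell plus one pooled row per
    species (block = "pooled"), with columns ``n, mean_lifespan,
    sd_lifespan, cv_lifespan, shape_mortality``.  A 3 species x 4 block
    design yields 12 cell rows, i.e. 12 cell-level shape values.
    """
    rows = []
    for sp in cohort.species:
        for bl in cohort.blocks:
            try:
                ls = lifespans(cohort, species=sp, block=bl)
            except EmptySelectionError:
                continue
            if len(ls) < 2:
                raise InsufficientDataError(
                    f"cell ({sp}, {bl}) has {len(ls)} included frond(s); "
                    "shape_mortality needs at least 2"
                )
            rows.append((sp, bl, ls))
        rows.append((sp, "pooled", lifespans(cohort, species=sp)))
    out = []
    for sp, bl, ls in rows:
        x = np.asarray(ls, dtype=float)
        out.append(
            {
                "species": sp,
                "block": bl,
                "n": x.size,
                "mean_lifespan": x.mean(),
                "sd_lifespan": x.std(ddof=1),
                "cv_lifespan": x.std(ddof=1) / x.mean(),
                "shape_mortality": shape_mortality(x),
            }
        )
    return pd.DataFrame(out)


def cell_mean_lifespans(cohort: Cohort) -> dict[tuple[str, str], float]:
    """Mean lifespan of included fronds per (species, block) cell."""
    table = pace_shape_table(cohort)
    cells = table[table["block"] != "pooled"]
    return {
        (r.species, r.block): r.mean_lifespan for r in cells.itertuples(index=False)
    }


def standardized_trajectory(
    frond: FrondRecord, cell_mean_lifespan: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pace-standardized age and mean-standardized fecundity for one frond.

    The window runs from first to last reproduction (zero-count days
    inside it included); x = age / cell mean lifespan, y = daily count /
    (total offspring / lifespan).
    """
    if cell_mean_lifespan <= 0:
        raise ValueError("cell_mean_lifespan must be > 0")
    if frond.excluded:
        raise ExclusionError(f"frond {frond.frond_id!r} is excluded")
    total = total_offspring(frond)
    if total == 0:
        raise ExclusionError(
            f"frond {frond.frond_id!r} has no offspring; cannot standardize"
        )
    ages = np.arange(frond.first_repro_age, frond.death_age + 1)
    counts = np.asarray(frond.daily_offspring[frond.first_repro_age - 1 :], dtype=float)
    mean_fec = total / frond.death_age
    return ages / cell_mean_lifespan, counts / mean_fec


def fecundity_slope(
    ages: Sequence[float],
    counts: Sequence[float],
    cell_mean_lifespan: float,
    lifespan: float,
) -> Optional[float]:
    """OLS slope of mean-standardized fecundity on pace-standardized age.

    The arithmetic primitive behind :func:`shape_fecundity`, operating on
    raw daily observations: ``x = age / cell_mean_lifespan`` and
    ``y = count / (sum(counts) / lifespan)``.  Returns ``None`` when fewer
    than two observations (no age variance, no slope).
    """
    x = np.asarray(ages, dtype=float) / cell_mean_lifespan
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("cannot standardize a window with zero total fecundity")
    y = c / (c.sum() / lifespan)
    if x.size < 2 or np.ptp(x) == 0:
        return None
    return float(np.polyfit(x, y, 1)[0])


@dataclass
class FecundityShapeRecord:
    """Per-frond reproductive-senescence slope and its regression window."""

    frond_id: str
    species: str
    block: str
    first_repro_age: int
    n_points: int
    shape_fecundity: Optional[float]
    defined: bool


def shape_fecundity(frond: FrondRecord, cell_mean_lifespan: float) -> FecundityShapeRecord:
    """OLS slope of the standardized fecundity trajectory of one frond.

    ``defined`` is False (slope ``None``) when the window has fewer than
    two daily observations, since a slope needs age variance.
    """
    x, _ = standardized_trajectory(frond, cell_mean_lifespan)
    ages = np.arange(frond.first_repro_age, frond.death_age + 1)
    counts = frond.daily_offspring[frond.first_repro_age - 1 :]
    slope = fecundity_slope(ages, counts, cell_mean_lifespan, frond.death_age)
    return FecundityShapeRecord(
        frond.frond_id,
        frond.species,
        frond.block,
        frond.first_repro_age,
        int(x.size),
        slope,
        slope is not None,
    )


def fecundity_shape_table(cohort: Cohort) -> pd.DataFrame:
    """shape_fecundity for every included frond, one row per frond.

    Fronds whose regression window is a single day get ``defined = False``
    and a logged count; downstream comparisons drop them.
    """
    means = cell_mean_lifespans(cohort)
    records = [
        shape_fecundity(f, means[(f.species, f.block)]) for f in cohort.included()
    ]
    n_undef = sum(not r.defined for r in records)
    if n_undef:
        logger.info("%d frond(s) with single-point windows: slope undefined", n_undef)
    return pd.DataFrame(
        {
            "frond_id": [r.frond_id for r in records],
            "species": [r.species for r in records],
            "block": [r.block for r in records],
            "first_repro_age": [r.first_repro_age for r in records],
            "n_points": [r.n_points for r in records],
            "shape_fecundity": [r.shape_fecundity for r in records],
            "defined": [r.defined for r in records],
        }
    )


def survivorship_curve(
    values: Sequence[float], standardized: bool = False
) -> pd.DataFrame:
    """Empirical survivorship step function from a set of lifespans.

    Returns (age, proportion) where proportion is the fraction of the
    cohort with lifespan >= age, evaluated at each age from 1 to one past
    the maximum (where it reaches 0).  ``standardized`` divides the age
    axis by the mean lifespan (pace standardization).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("survivorship_curve needs >= 1 lifespan")
    ages = np.arange(1, int(x.max()) + 2)
    prop = np.array([(x >= a).mean() for a in ages])
    axis = ages / x.mean() if standardized else ages.astype(float)
    return pd.DataFrame({"age": axis, "surviving": prop})


def reproduction_proportion_curve(cohort: Cohort, species: str) -> pd.DataFrame:
    """Proportion of surviving fronds reproducing at each age, one species.

    At each age up to the species' maximum lifespan, the denominator is
    the number of included fronds still alive (death_age >= age) and the
    numerator those with a positive count that day.  The denominator
    dwindles at old ages, so late proportions are noisy.
    """
    fronds = cohort.included(species=species)
    if not fronds:
        raise EmptySelectionError(f"no included fronds for species {species!r}")
    max_age = max(f.death_age for f in fronds)
    rows = []
    for a in range(1, max_age + 1):
        alive = [f for f in fronds if f.death_age >= a]
        repro = sum(f.daily_offspring[a - 1] >= 1 for f in alive)
        rows.append(
            {
                "age": a,
                "n_alive": len(alive),
                "proportion_reproducing": repro / len(alive),
            }
        )
    return pd.DataFrame(rows)
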