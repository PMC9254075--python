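"""Per-frond daily demography records: data model, validation, and CSV I/O.

The demographic individual is a duckweed frond (ramet).  A frond is "born"
the day it detaches from its parent and is operationally "dead" on the day
its final daughter detaches, so an included frond's daily offspring sequence
always ends with a positive count.  Ages are integer days, age 1 being the
first full day after detachment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: columns a long-format cohort CSV must have
REQUIRED_COLUMNS = ("frond_id", "species", "block", "age_day", "offspring_count")
#: optional per-frond columns (constant within a frond)
OPTIONAL_COLUMNS = ("excluded", "exclusion_reason", "surface_area", "perimeter")


class CohortFormatError(ValueError):
    """The CSV does not have the long-format cohort schema."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant."""


class EmptySelectionError(LookupError):
    """A species/block filter matched no included fronds."""


class ExclusionError(ValueError):
    """An operation that requires an included frond was given an excluded one."""


@dataclass
class FrondRecord:
    """One ramet's labels and daily offspring counts from birth to death.

    ``daily_offspring[a - 1]`` is the number of daughters that detached on
    age-day ``a``.  Counts are stored as integers (not booleans) because
    total reproductive output counts a two-daughter day as 2, while the
    marginal reproduction model binarizes.
    """

    frond_id: str
    species: str
    block: str
    daily_offspring: list[int] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    surface_area: Optional[float] = None  # mm^2
    perimeter: Optional[float] = None  # mm

    def __post_init__(self) -> None:
        self.daily_offspring = [int(c) for c in self.daily_offspring]
        self.validate()

    def validate(self) -> None:
        for a, c in enumerate(self.daily_offspring, start=1):
            if c < 0:
                raise CohortValidationError(
                    f"frond {self.frond_id!r}: negative count {c} at age {a}"
                )
            if c > 2:
                warnings.warn(
                    f"frond {self.frond_id!r}: count {c} > 2 at age {a} "
                    "(daily broods are typically 0 or 1, rarely 2)",
                    stacklevel=2,
                )
        if not self.excluded:
            if not self.daily_offspring:
                raise CohortValidationError(
                    f"included frond {self.frond_id!r} has no observations"
                )
            if self.daily_offspring[-1] < 1:
                raise CohortValidationError(
                    f"included frond {self.frond_id!r} ends with a zero count; "
                    "death is operationally the day of final reproduction"
                )
        if self.surface_area is not None and self.surface_area <= 0:
            raise CohortValidationError(
                f"frond {self.frond_id!r}: surface_area must be positive"
            )
        if self.perimeter is not None and self.perimeter <= 0:
            raise CohortValidationError(
                f"frond {self.frond_id!r}: perimeter must be positive"
            )

    @property
    def death_age(self) -> int:
        """Age in days of the final reproduction event (= lifespan)."""
        if self.excluded:
            raise ExclusionError(f"frond {self.frond_id!r} is excluded")
        return len(self.daily_offspring)

    @property
    def first_repro_age(self) -> int:
        """Age of the first positive daily count."""
        if self.excluded:
            raise ExclusionError(f"frond {self.frond_id!r} is excluded")
        for a, c in enumerate(self.daily_offspring, start=1):
            if c > 0:
                return a
        raise CohortValidationError(
            f"included frond {self.frond_id!r} never reproduced"
        )


@dataclass
class Cohort:
    """A validated collection of :class:`FrondRecord` with free-form metadata."""

    fronds: list[FrondRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.frond_id for f in self.fronds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate frond_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.fronds)

    @property
    def species(self) -> list[str]:
        """Distinct species labels, in first-appearance order."""
        return list(dict.fromkeys(f.species for f in self.fronds))

    @property
    def blocks(self) -> list[str]:
        return list(dict.fromkeys(f.block for f in self.fronds))

    def included(
        self, species: Optional[str] = None, block: Optional[str] = None
    ) -> list[FrondRecord]:
        """Included fronds, optionally restricted to a species and/or block."""
        return [
            f
            for f in self.fronds
            if not f.excluded
            and (species is None or f.species == species)
            and (block is None or f.block == block)
        ]


def total_offspring(frond: FrondRecord) -> int:
    """Lifetime reproductive output: the sum of a frond's daily counts."""
    if frond.excluded:
        raise ExclusionError(f"frond {frond.frond_id!r} is excluded")
    return sum(frond.daily_offspring)


def lifespans(
    cohort: Cohort, species: Optional[str] = None, block: Optional[str] = None
) -> list[int]:
    """Reproductive lifespans (days) of the included fronds matching a filter.

    The lifespan of a frond is the time from detachment to the day of final
    reproduction, i.e. its ``death_age``.  Excluded fronds never contribute.

    Raises
    ------
    EmptySelectionError
        If the filter matches no included frond, so callers cannot mistake
        a bad label for an empty cohort.
    """
    selected = cohort.included(species=species, block=block)
    if not selected:
        raise EmptySelectionError(
            f"no included fronds for species={species!r}, block={block!r}"
        )
    return [f.death_age for f in selected]


def _densify(ages: Sequence[int], counts: Sequence[int], excluded: bool) -> list[int]:
    """Spread sparse (age, count) rows onto a dense 1..max(age) grid.

    Unobserved intermediate ages get count 0; for included fronds, trailing
    zero days after the last positive count are trimmed (death is the final
    reproduction day, so they carry no information).
    """
    by_age = dict(zip(ages, counts))
    dense = [by_age.get(a, 0) for a in range(1, max(ages) + 1)]
    if not excluded:
        while dense and dense[-1] == 0:
            dense.pop()
    return dense


def read_cohort(path) -> Cohort:
    """Read a long-format cohort CSV (one row per frond-age).

    Required columns: ``frond_id, species, block, age_day, offspring_count``.
    Optional per-frond columns (``excluded, exclusion_reason, surface_area,
    perimeter``) must be constant within each frond.
    """
    df = pd.read_csv(
        path,
        dtype={"frond_id": str, "species": str, "block": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {missing}")

    for col in ("age_day", "offspring_count"):
        vals = df[col]
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = int(bad.idxmax())
            raise CohortValidationError(
                f"non-integer or missing {col} at CSV row {row + 2}"
            )
    if (df["offspring_count"] < 0).any():
        row = int((df["offspring_count"] < 0).idxmax())
        raise CohortValidationError(f"negative offspring_count at CSV row {row + 2}")
    if (df["age_day"] < 1).any():
        row = int((df["age_day"] < 1).idxmax())
        raise CohortValidationError(f"age_day < 1 at CSV row {row + 2}")

    fronds = []
    for fid, sub in df.groupby("frond_id", sort=True):
        consts = {}
        for col in ("species", "block", *OPTIONAL_COLUMNS):
            if col not in sub.columns:
                consts[col] = None
                continue
            uniq = sub[col].dropna().unique()
            if len(uniq) > 1:
                raise CohortValidationError(
                    f"frond {fid!r}: column {col!r} is not constant within frond"
                )
            consts[col] = uniq[0] if len(uniq) else None
        if sub["age_day"].duplicated().any():
            raise CohortValidationError(f"frond {fid!r}: duplicated age_day rows")
        excluded = bool(consts["excluded"]) if consts["excluded"] is not None else False
        dense = _densify(
            sub["age_day"].astype(int).tolist(),
            sub["offspring_count"].astype(int).tolist(),
            excluded,
        )
        fronds.append(
            FrondRecord(
                frond_id=str(fid),
                species=str(consts["species"]),
                block=str(consts["block"]),
                daily_offspring=dense,
                excluded=excluded,
                exclusion_reason=(
                    str(consts["exclusion_reason"])
                    if consts["exclusion_reason"] is not None
                    else None
                ),
                surface_area=(
                    float(consts["surface_area"])
                    if consts["surface_area"] is not None
                    else None
                ),
                perimeter=(
                    float(consts["perimeter"])
                    if consts["perimeter"] is not None
                    else None
                ),
            )
        )
    return Cohort(fronds=fronds)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as a long-format CSV with deterministic row order.

    Rows are sorted by ``frond_id`` then ``age_day`` so the file is
    bit-stable for a given cohort.
    """
    rows = []
    for f in sorted(cohort.fronds, key=lambda f: f.frond_id):
        for a, c in enumerate(f.daily_offspring, start=1):
            rows.append(
                {
                    "frond_id": f.frond_id,
                    "species": f.species,
                    "block": f.block,
                    "age_day": a,
                    "offspring_count": c,
                    "excluded": f.excluded,
                    "exclusion_reason": f.exclusion_reason,
                    "surface_area": f.surface_area,
                    "perimeter": f.perimeter,
                }
            )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
    # %.17g keeps the size traits bit-exact across a write/read round trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_size_traits(cohort: Cohort, path) -> None:
    """Attach per-frond size traits from a companion CSV, in place.

    Expected columns: ``frond_id, surface_area_mm2, perimeter_mm``.
    """
    df = pd.read_csv(path, dtype={"frond_id": str})
    missing = [
        c for c in ("frond_id", "surface_area_mm2", "perimeter_mm") if c not in df.columns
    ]
    if missing:
        raise CohortFormatError(f"size-trait CSV missing column(s): {missing}")
    traits = df.set_index("frond_id")
    by_id = {f.frond_id: f for f in cohort.fronds}
    for fid, row in traits.iterrows():
        if fid in by_id:
            by_id[fid].surface_area = float(row["surface_area_mm2"])
            by_id[fid].perimeter = float(row["perimeter_mm"])
            by_id[fid].validate()
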