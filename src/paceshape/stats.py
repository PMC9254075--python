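"""Cross-species trait comparisons: two-way ANOVA and Tukey-Kramer tests.

Each demographic or size trait is compared across species and blocks with
a two-way ANOVA using sequential (Type I) sums of squares, Species entered
first, then Block, then their interaction.  The cell-level mortality-shape
trait has a single value per species-block cell, so its ANOVA has no
interaction term.  Significant species effects are followed by
Tukey-Kramer all-pairs comparisons (studentized-range based, valid for
unequal group sizes) summarized as a compact letter display: species that
share a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from statsmodels.stats.anova import anova_lm

from .cohort import Cohort, total_offspring
from .pace_shape import fecundity_shape_table, pace_shape_table

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """One two-way ANOVA table plus the residual quantities post hoc tests need."""

    response_name: str
    transform: str  # "none" | "log"
    table: pd.DataFrame  # Source, df, SS, MS, F, p
    mse_resid: float
    df_resid: int

    def source_row(self, source: str) -> pd.Series:
        return self.table.set_index("Source").loc[source]


def two_way_anova(
    values: Sequence[float],
    species_labels: Sequence[str],
    block_labels: Sequence[str],
    interaction: bool = True,
    ss_type: int = 1,
) -> AnovaResult:
    """Two-way ANOVA of a trait on Species and Block.

    Sequential (Type I) sums of squares by default, Species first; a Type
    II decomposition is available via ``ss_type=2``.  ``interaction=False``
    fits main effects only — required when each cell holds one value, as
    for the cell-level mortality-shape trait.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "species": list(species_labels),
            "block": list(block_labels),
        }
    )
    if df["species"].nunique() < 2 or df["block"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["species", "block"], observed=True).size()
    formula = "value ~ C(species) + C(block)"
    if interaction:
        if (cells < 2).any() and len(df) == len(cells):
            raise ValueError(
                "one value per cell: interaction is not estimable; "
                "call with interaction=False"
            )
        formula += " + C(species):C(block)"
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("residual degrees of freedom < 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-SS edge cases
        raw = anova_lm(fit, typ=ss_type)

    name_map = {
        "C(species)": "Species",
        "C(block)": "Block",
        "C(species):C(block)": "Species x Block",
        "Residual": "Residual",
    }
    rows = []
    for src, r in raw.iterrows():
        rows.append(
            {
                "Source": name_map.get(src, src),
                "df": int(r["df"]),
                "SS": float(r["sum_sq"]),
                "MS": float(r["sum_sq"]) / r["df"],
                "F": float(r["F"]) if np.isfinite(r.get("F", np.nan)) else np.nan,
                "p": float(r["PR(>F)"])
                if np.isfinite(r.get("PR(>F)", np.nan))
                else np.nan,
            }
        )
    resid = next(r for r in rows if r["Source"] == "Residual")
    if resid["SS"] == 0:
        warnings.warn("zero residual variance: F reported as inf, p = 0")
        for r in rows:
            if r["Source"] != "Residual" and r["SS"] > 0:
                r["F"], r["p"] = np.inf, 0.0
    rows.append(
        {
            "Source": "Total",
            "df": sum(r["df"] for r in rows),
            "SS": sum(r["SS"] for r in rows),
            "MS": np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows, columns=["Source", "df", "SS", "MS", "F", "p"])
    return AnovaResult(
        response_name="value",
        transform="none",
        table=table,
        mse_resid=resid["MS"],
        df_resid=resid["df"],
    )


def _compact_letters(
    groups: Sequence[str], means: dict[str, float], sig: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column containing every group; each significantly
    different pair splits any column containing both; columns that become
    subsets of another are absorbed.  Letters are assigned in order of
    descending group mean.
    """
    order = sorted(groups, key=lambda g: -means[g])
    columns: list[set] = [set(order)]
    for pair in sig:
        i, j = tuple(pair)
        split: list[set] = []
        for col in columns:
            if i in col and j in col:
                split.extend([col - {i}, col - {j}])
            else:
                split.append(col)
        # absorb: drop empties, strict subsets of another column, and duplicates
        columns = []
        for c in split:
            if c and not any(c < d for d in split) and c not in columns:
                columns.append(c)
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


@dataclass
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons plus a compact letter display."""

    pairwise: pd.DataFrame  # group1, group2, mean_diff, q, p_adj, significant
    letters: dict[str, str]
    alpha: float


def tukey_kramer(
    values: Sequence[float],
    group_labels: Sequence[str],
    mse: float,
    df_resid: int,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey-Kramer all-pairs comparison with an external error variance.

    ``mse`` and ``df_resid`` come from the ANOVA whose model defines the
    error term (here the two-way model), so the post hoc test and the
    omnibus test share an error estimate.  For pair (i, j):
    ``q = |m_i - m_j| / sqrt(mse/2 * (1/n_i + 1/n_j))`` referred to the
    studentized range with (k, df_resid); with equal n this is plain
    Tukey HSD.
    """
    if df_resid < 1:
        raise ValueError("df_resid must be >= 1")
    if mse <= 0:
        raise ValueError("mse must be > 0")
    s = pd.Series(np.asarray(values, dtype=float), index=list(group_labels))
    groups = list(dict.fromkeys(group_labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    means = {g: s[s.index == g].mean() for g in groups}
    ns = {g: int((s.index == g).sum()) for g in groups}
    rows = []
    sig = set()
    for g1, g2 in itertools.combinations(groups, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, df_resid))
        if p < alpha:
            sig.add(frozenset((g1, g2)))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean_diff": diff,
                "q": q,
                "p_adj": p,
                "significant": p < alpha,
            }
        )
    letters = _compact_letters(groups, means, sig)
    return TukeyResult(pairwise=pd.DataFrame(rows), letters=letters, alpha=alpha)


@dataclass
class TraitComparison:
    """ANOVA (and Tukey letters where Species is significant) for one trait."""

    response: str
    transform: str
    anova: AnovaResult
    tukey: Optional[TukeyResult] = None


def trait_comparison(
    cohort: Cohort, alpha: float = 0.05, ss_type: int = 1
) -> dict[str, TraitComparison]:
    """The six standard trait analyses for a species-by-block cohort.

    Responses: log(lifespan), cell-level mortality shape (no interaction),
    total offspring, fecundity shape, log(surface area) and log(perimeter)
    (the last two skipped with a notice when size traits are absent).
    Natural logs; Tukey-Kramer on Species whenever its p < alpha.
    """
    fronds = cohort.included()
    per_frond = pd.DataFrame(
        {
            "species": [f.species for f in fronds],
            "block": [f.block for f in fronds],
            "lifespan": [f.death_age for f in fronds],
            "total_offspring": [total_offspring(f) for f in fronds],
            "surface_area": [f.surface_area for f in fronds],
            "perimeter": [f.perimeter for f in fronds],
        }
    )
    analyses: list[tuple[str, str, pd.DataFrame, str, bool]] = []
    analyses.append(("log(lifespan)", "log", per_frond, "lifespan", True))

    cells = pace_shape_table(cohort)
    cells = cells[cells["block"] != "pooled"].rename(
        columns={"shape_mortality": "value_col"}
    )
    analyses.append(("shape_mortality", "none", cells, "value_col", False))
    analyses.append(("total_offspring", "none", per_frond, "total_offspring", True))

    fec = fecundity_shape_table(cohort)
    fec_ok = fec[fec["defined"]].copy()
    n_undef = int((~fec["defined"]).sum())
    if n_undef:
        logger.info("dropping %d undefined fecundity-shape slope(s)", n_undef)
    analyses.append(("shape_fecundity", "none", fec_ok, "shape_fecundity", True))

    if per_frond["surface_area"].notna().all():
        analyses.append(("log(surface_area)", "log", per_frond, "surface_area", True))
        analyses.append(("log(perimeter)", "log", per_frond, "perimeter", True))
    else:
        logger.info("size traits absent; skipping surface area and perimeter ANOVAs")

    out: dict[str, TraitComparison] = {}
    for name, transform, frame, col, interaction in analyses:
        y = frame[col].astype(float)
        if transform == "log":
            y = np.log(y)
        res = two_way_anova(
            y, frame["species"], frame["block"], interaction=interaction, ss_type=ss_type
        )
        res.response_name = name
        res.transform = transform
        tukey = None
        if res.source_row("Species")["p"] < alpha:
            tukey = tukey_kramer(
                y, frame["species"].tolist(), res.mse_resid, res.df_resid, alpha
            )
        out[name] = TraitComparison(name, transform, res, tukey)
    return out
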