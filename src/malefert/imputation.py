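"""Imputation of births with unknown paternal age.

The conditional approach allocates each (year, maternal age) cell's
unknown-father births across paternal ages in proportion to the father-age
distribution observed among known-father births to mothers of that same age
and year. The mother's age is an excellent predictor of the father's age, so
conditioning on it preserves the joint age structure that unconditional
(marginal) allocation destroys. The unconditional approach is provided as a
comparator.

Allocation is deterministic and fractional (expected counts, no rounding);
per-year totals are conserved exactly. Imputation never borrows across
calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import (
    MALE_AGES,
    UNKNOWN,
    BirthTable,
    ImputationError,
)

#: widest symmetric maternal-age window tried before falling back to the
#: year's marginal father distribution
MAX_POOLING_WINDOW = 5


@dataclass
class ConditionalFatherDistribution:
    """Father-age distributions conditional on (year, maternal age).

    ``dists[(year, mother_age)]`` is a probability vector over paternal ages
    15-59 summing to 1.  ``marginal[year]`` is the year's marginal
    known-father distribution (the final pooling fallback).
    """

    dists: dict[tuple[int, int], pd.Series]
    marginal: dict[int, pd.Series]

    def prob(self, year: int, mother_age: int) -> pd.Series:
        return self.dists[(year, mother_age)]


def _normalize(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    return counts.reindex(MALE_AGES, fill_value=0.0) / total


def fit_conditional_distribution(
    births: BirthTable, pooling_policy: str = "widening"
) -> ConditionalFatherDistribution:
    """Fit father-age distributions conditional on maternal age, per year.

    For each (year, maternal age) present in the data the distribution is
    proportional to the known-father counts in that cell. Maternal ages with
    no known-father births are resolved by a symmetric widening window over
    maternal ages (+-1, +-2, ... up to +-``MAX_POOLING_WINDOW``); the first
    window with any known-father births wins, and the final fallback is the
    year's marginal father distribution.

    Raises
    ------
    ImputationError
        If a year has no known-father births at all.
    """
    if pooling_policy not in ("widening", "marginal"):
        raise ValueError(f"unknown pooling_policy {pooling_policy!r}")
    dists: dict[tuple[int, int], pd.Series] = {}
    marginal: dict[int, pd.Series] = {}
    for year, sub in births.df.groupby("year"):
        known = sub[(sub["father_age"] != UNKNOWN) & (sub["mother_age"] != UNKNOWN)]
        if known["count"].sum() <= 0:
            raise ImputationError(
                f"year {year}: no births with both parental ages known; "
                "imputation impossible"
            )
        marginal[year] = _normalize(known.groupby("father_age")["count"].sum())
        by_mother = known.groupby(["mother_age", "father_age"])["count"].sum()
        mother_ages = sorted(sub.loc[sub["mother_age"] != UNKNOWN, "mother_age"].unique())
        for m in mother_ages:
            cell = by_mother.loc[m] if m in by_mother.index.get_level_values(0) else None
            if cell is not None and cell.sum() > 0:
                dists[(year, m)] = _normalize(cell)
                continue
            if pooling_policy == "marginal":
                dists[(year, m)] = marginal[year]
                continue
            pooled = None
            for w in range(1, MAX_POOLING_WINDOW + 1):
                window = known[known["mother_age"].between(m - w, m + w)]
                if window["count"].sum() > 0:
                    pooled = _normalize(window.groupby("father_age")["count"].sum())
                    break
            dists[(year, m)] = pooled if pooled is not None else marginal[year]
    return ConditionalFatherDistribution(dists, marginal)


def _allocate_joint_unknowns(df: pd.DataFrame) -> pd.DataFrame:
    """Spread births with both ages unknown over the year's known joint cells."""
    out_frames = [df[(df["mother_age"] != UNKNOWN) | (df["father_age"] != UNKNOWN)]]
    both = df[(df["mother_age"] == UNKNOWN) & (df["father_age"] == UNKNOWN)]
    for row in both.itertuples(index=False):
        year_df = df[df["year"] == row.year]
        known = year_df[
            (year_df["mother_age"] != UNKNOWN) & (year_df["father_age"] != UNKNOWN)
        ]
        total = known["count"].sum()
        if total <= 0:
            raise ImputationError(
                f"year {row.year}: no fully known births to allocate "
                "double-unknown births over"
            )
        alloc = known.copy()
        alloc["count"] = known["count"] / total * row.count
        out_frames.append(alloc)
    return pd.concat(out_frames, ignore_index=True)


def conditional_impute(births: BirthTable) -> BirthTable:
    """Impute unknown paternal ages conditional on the mother's age.

    Each (year, maternal age) cell's unknown-father count is multiplied into
    paternal-age cells proportionally to the fitted conditional distribution.
    Births with both ages unknown are spread over the year's known joint
    distribution; births with an unknown mother but a known father are kept
    as-is (they still contribute to male rates). Per-year totals conserved;
    the output has no unknown paternal ages.
    """
    if not births.has_unknown_father():
        return births.copy()
    cond = fit_conditional_distribution(births)
    df = _allocate_joint_unknowns(births.df)
    keep = df[df["father_age"] != UNKNOWN]
    frames = [keep]
    todo = df[(df["father_age"] == UNKNOWN) & (df["count"] > 0)]
    for row in todo.itertuples(index=False):
        probs = cond.prob(row.year, row.mother_age)
        nz = probs[probs > 0]
        frames.append(
            pd.DataFrame(
                {
                    "year": row.year,
                    "mother_age": row.mother_age,
                    "father_age": nz.index,
                    "count": nz.to_numpy() * row.count,
                }
            )
        )
    return BirthTable(pd.concat(frames, ignore_index=True))


def unconditional_impute(births: BirthTable) -> BirthTable:
    """Impute unknown paternal ages from the year's marginal distribution.

    The comparator approach: unknown-father counts are allocated
    proportionally to the year's marginal father-age distribution among
    known-father births, ignoring the mother's age. Totals conserved.
    """
    if not births.has_unknown_father():
        return births.copy()
    cond = fit_conditional_distribution(births)  # reuses the marginal + checks
    df = _allocate_joint_unknowns(births.df)
    keep = df[df["father_age"] != UNKNOWN]
    frames = [keep]
    todo = df[(df["father_age"] == UNKNOWN) & (df["count"] > 0)]
    for row in todo.itertuples(index=False):
        probs = cond.marginal[row.year]
        nz = probs[probs > 0]
        frames.append(
            pd.DataFrame(
                {
                    "year": row.year,
                    "mother_age": row.mother_age,
                    "father_age": nz.index,
                    "count": nz.to_numpy() * row.count,
                }
            )
        )
    return BirthTable(pd.concat(frames, ignore_index=True))
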