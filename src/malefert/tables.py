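"""Core data containers for two-sex fertility analysis.

All tables live on 1-year age x 1-year period Lexis squares with ages as
completed years (age last birthday), following HFD/HFC conventions.  Female
reproductive ages are 15-49; male ages are 15-59.  Unknown parental ages are
encoded with the integer sentinel :data:`UNKNOWN` internally and with the
token ``"UNK"`` in all file dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# -- age conventions ---------------------------------------------------------

FEMALE_AGE_MIN, FEMALE_AGE_MAX = 15, 49
MALE_AGE_MIN, MALE_AGE_MAX = 15, 59
#: cohort fertility sums rates over ages 15..50 inclusive
CFR_AGE_MIN, CFR_AGE_MAX = 15, 50

FEMALE_AGES = np.arange(FEMALE_AGE_MIN, FEMALE_AGE_MAX + 1)
MALE_AGES = np.arange(MALE_AGE_MIN, MALE_AGE_MAX + 1)

#: integer sentinel for an unknown parental age
UNKNOWN = -1
#: token used for unknown ages in every file dialect
UNK_TOKEN = "UNK"


def age_support(sex: str) -> np.ndarray:
    """Full single-age support for one sex ('female': 15-49, 'male': 15-59)."""
    if sex == "female":
        return FEMALE_AGES
    if sex == "male":
        return MALE_AGES
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


# -- errors ------------------------------------------------------------------


class MalefertError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MalefertError):
    """Invalid scenario or pipeline configuration."""


class DataError(MalefertError):
    """Inconsistent or invalid table content (e.g. births without exposure)."""


class ParseError(MalefertError):
    """Malformed input file; carries a line number where possible."""


class ImputationError(MalefertError):
    """Imputation impossible (e.g. a year with no known-father births)."""


class NumericError(MalefertError):
    """A numerical routine failed to converge."""


class IncompleteCohortError(MalefertError):
    """Cohort fertility requested for a cohort with missing years."""

    def __init__(self, cohort: int, missing_years: Iterable[int]):
        self.cohort = cohort
        self.missing_years = sorted(missing_years)
        super().__init__(
            f"incomplete cohort {cohort}: missing years {self.missing_years}"
        )


# -- BirthTable --------------------------------------------------------------


@dataclass
class BirthTable:
    """Birth counts by (year, maternal age, paternal age).

    ``df`` has columns ``year``, ``mother_age``, ``father_age``, ``count``.
    Ages are completed years; :data:`UNKNOWN` marks a missing parental age.
    Counts are non-negative reals: integers before imputation, fractional
    counts are permitted after proportional allocation.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["year", "mother_age", "father_age", "count"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise DataError(f"BirthTable missing columns {missing}")
        df = self.df[required].copy()
        df["year"] = df["year"].astype(int)
        df["mother_age"] = df["mother_age"].astype(int)
        df["father_age"] = df["father_age"].astype(int)
        df["count"] = df["count"].astype(float)
        if not np.isfinite(df["count"]).all():
            raise DataError("non-finite birth count")
        if (df["count"] < 0).any():
            bad = df[df["count"] < 0].iloc[0]
            raise DataError(
                f"negative birth count at (year={bad.year}, "
                f"mother={bad.mother_age}, father={bad.father_age})"
            )
        ok_mother = (df["mother_age"] == UNKNOWN) | df["mother_age"].between(
            FEMALE_AGE_MIN, FEMALE_AGE_MAX
        )
        if not ok_mother.all():
            raise DataError(
                f"maternal age outside {FEMALE_AGE_MIN}-{FEMALE_AGE_MAX}: "
                f"{sorted(df.loc[~ok_mother, 'mother_age'].unique())}"
            )
        ok_father = (df["father_age"] == UNKNOWN) | df["father_age"].between(
            MALE_AGE_MIN, MALE_AGE_MAX
        )
        if not ok_father.all():
            raise DataError(
                f"paternal age outside {MALE_AGE_MIN}-{MALE_AGE_MAX}: "
                f"{sorted(df.loc[~ok_father, 'father_age'].unique())}"
            )
        df = (
            df.groupby(["year", "mother_age", "father_age"], as_index=False)["count"]
            .sum()
            .sort_values(["year", "mother_age", "father_age"])
            .reset_index(drop=True)
        )
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, int, int, float]]
    ) -> "BirthTable":
        """Build from (year, mother_age, father_age, count) tuples."""
        df = pd.DataFrame(
            records, columns=["year", "mother_age", "father_age", "count"]
        )
        return cls(df)

    def copy(self) -> "BirthTable":
        return BirthTable(self.df.copy())

    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def total(self) -> float:
        return float(self.df["count"].sum())

    def totals_by_year(self) -> pd.Series:
        return self.df.groupby("year")["count"].sum()

    def has_unknown_father(self) -> bool:
        mask = (self.df["father_age"] == UNKNOWN) & (self.df["count"] > 0)
        return bool(mask.any())

    def has_unknown_mother(self) -> bool:
        mask = (self.df["mother_age"] == UNKNOWN) & (self.df["count"] > 0)
        return bool(mask.any())

    def births_by_age(self, sex: str, year: int) -> pd.Series:
        """Births of one year attributed to the given parent's age.

        Raises :class:`DataError` if that parent's age is unknown for any
        birth with positive count in the year.
        """
        col = "father_age" if sex == "male" else "mother_age"
        sub = self.df[self.df["year"] == year]
        unk = sub[(sub[col] == UNKNOWN) & (sub["count"] > 0)]
        if len(unk):
            raise DataError(
                f"{col} unknown for {unk['count'].sum():g} births in {year}; "
                "impute before computing rates"
            )
        out = sub.groupby(col)["count"].sum()
        return out.reindex(age_support(sex), fill_value=0.0)


# -- ExposureTable -----------------------------------------------------------


@dataclass
class ExposureTable:
    """Person-years of exposure by (sex, age, year).

    ``df`` has columns ``sex``, ``age``, ``year``, ``exposure``; the rate
    denominator for every fertility measure in the package.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sex", "age", "year", "exposure"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise DataError(f"ExposureTable missing columns {missing}")
        df = self.df[required].copy()
        if not df["sex"].isin(["male", "female"]).all():
            bad = sorted(set(df["sex"]) - {"male", "female"})
            raise DataError(f"unknown sex labels {bad}")
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["exposure"] = df["exposure"].astype(float)
        if not np.isfinite(df["exposure"]).all() or (df["exposure"] < 0).any():
            raise DataError("exposures must be finite and non-negative")
        for sex in ("female", "male"):
            ages = df.loc[df["sex"] == sex, "age"]
            if len(ages):
                lo, hi = age_support(sex)[[0, -1]]
                if ages.min() < lo or ages.max() > hi:
                    raise DataError(f"{sex} exposure age outside {lo}-{hi}")
        df = (
            df.groupby(["sex", "age", "year"], as_index=False)["exposure"]
            .sum()
            .sort_values(["sex", "year", "age"])
            .reset_index(drop=True)
        )
        self.df = df

    def copy(self) -> "ExposureTable":
        return ExposureTable(self.df.copy())

    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def series(self, sex: str, year: int) -> pd.Series:
        """Exposure by age for one sex and year on the sex's full support."""
        sub = self.df[(self.df["sex"] == sex) & (self.df["year"] == year)]
        s = sub.set_index("age")["exposure"]
        return s.reindex(age_support(sex), fill_value=np.nan)


# -- ASFRSchedule ------------------------------------------------------------


@dataclass
class ASFRSchedule:
    """Single-age fertility rates for one sex and year.

    ``rates`` is indexed by age on the sex's full support (15-49 for women,
    15-59 for men), in births per person-year.
    """

    sex: str
    year: int
    rates: pd.Series

    def __post_init__(self) -> None:
        support = age_support(self.sex)
        rates = self.rates.reindex(support)
        if rates.isna().any():
            missing = list(rates.index[rates.isna()])
            raise DataError(f"{self.sex} schedule missing ages {missing}")
        if not np.isfinite(rates).all() or (rates < 0).any():
            raise DataError("ASFRs must be finite and non-negative")
        self.rates = rates.astype(float)

    def copy(self) -> "ASFRSchedule":
        return ASFRSchedule(self.sex, self.year, self.rates.copy())


# -- SummaryIndicators -------------------------------------------------------


@dataclass
class SummaryIndicators:
    """Male/female comparison indicators for one year (or cohort)."""

    year: int
    male_tfr: float
    female_tfr: float
    tfr_ratio: float
    mac_male: float
    mac_female: float
    mac_difference: float
    cfr_male: float | None = None
    cfr_female: float | None = None
    cfr_ratio: float | None = None

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "year": self.year,
            "male_tfr": self.male_tfr,
            "female_tfr": self.female_tfr,
            "tfr_ratio": self.tfr_ratio,
            "mac_male": self.mac_male,
            "mac_female": self.mac_female,
            "mac_difference": self.mac_difference,
            "cfr_male": self.cfr_male,
            "cfr_female": self.cfr_female,
            "cfr_ratio": self.cfr_ratio,
        }
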