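"""Age-specific fertility rates and summary indicators.

Rates are events over person-years on 1x1 Lexis squares. The period TFR sums
a year's ASFRs over the sex's reproductive range (15-49 women, 15-59 men);
the cohort CFR sums rates along the cohort's diagonal through period
schedules, restricted to ages 15-50; the mean age at childbirth (MAC) is the
ASFR-weighted mean age using completed-age midpoints (age + 0.5).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    CFR_AGE_MAX,
    CFR_AGE_MIN,
    ASFRSchedule,
    BirthTable,
    DataError,
    ExposureTable,
    IncompleteCohortError,
    SummaryIndicators,
    age_support,
)


def compute_asfr(
    births: BirthTable,
    exposures: ExposureTable,
    sex: str,
    year: int | None = None,
) -> ASFRSchedule:
    """ASFR schedule for one sex and year: births / person-years by age.

    The relevant parental age must be known for every birth in the year
    (impute first). Ages with zero exposure and zero births get rate 0;
    births with zero exposure are a data error naming the cell.
    """
    if year is None:
        years = births.years()
        if len(years) != 1:
            raise ValueError("year must be given for a multi-year table")
        year = years[0] if years else exposures.years()[0]
    b = births.births_by_age(sex, year)
    e = exposures.series(sex, year)
    if e.isna().any():
        missing = list(e.index[e.isna()])
        raise DataError(f"{sex} exposure missing for ages {missing} in {year}")
    rates = pd.Series(0.0, index=b.index)
    pos = e > 0
    rates[pos] = b[pos] / e[pos]
    bad = (~pos) & (b > 0)
    if bad.any():
        age = int(b.index[bad][0])
        raise DataError(
            f"{b[bad].sum():g} births with zero {sex} exposure at "
            f"(age={age}, year={year})"
        )
    return ASFRSchedule(sex, int(year), rates)


def asfr_series(
    births: BirthTable, exposures: ExposureTable, sex: str
) -> dict[int, ASFRSchedule]:
    """Period schedules for every year present in the birth table."""
    return {y: compute_asfr(births, exposures, sex, y) for y in births.years()}


def tfr(schedule: ASFRSchedule) -> float:
    """Period total fertility rate: sum of single-age rates."""
    return float(schedule.rates.sum())


def cfr(schedules: Mapping[int, ASFRSchedule], cohort: int) -> float:
    """Cohort fertility rate along the period-age diagonal, ages 15-50.

    Uses rate(age x) from the period schedule of year ``cohort + x``. Ages
    outside the sex's support (e.g. age 50 for women) contribute 0, but the
    year itself must be present.

    Raises
    ------
    IncompleteCohortError
        If any year ``cohort+15 .. cohort+50`` is missing.
    """
    needed = range(cohort + CFR_AGE_MIN, cohort + CFR_AGE_MAX + 1)
    missing = [y for y in needed if y not in schedules]
    if missing:
        raise IncompleteCohortError(cohort, missing)
    total = 0.0
    for age in range(CFR_AGE_MIN, CFR_AGE_MAX + 1):
        sched = schedules[cohort + age]
        if age in sched.rates.index:
            total += float(sched.rates[age])
    return total


def mac(schedule: ASFRSchedule) -> float:
    """Mean age at childbirth with completed-age midpoints (age + 0.5)."""
    total = schedule.rates.sum()
    if total <= 0:
        raise DataError(
            f"MAC undefined: all-zero {schedule.sex} schedule in {schedule.year}"
        )
    ages = schedule.rates.index.to_numpy(dtype=float) + 0.5
    return float((ages * schedule.rates.to_numpy()).sum() / total)


def compare(male: ASFRSchedule, female: ASFRSchedule) -> SummaryIndicators:
    """Male/female quantum and tempo comparison for one year.

    tfr_ratio = male TFR / female TFR (1 means equal quantum);
    mac_difference = male MAC - female MAC, in years.
    """
    if male.year != female.year:
        raise ValueError(
            f"schedules from different years ({male.year} vs {female.year})"
        )
    male_tfr, female_tfr = tfr(male), tfr(female)
    if female_tfr <= 0:
        raise DataError(f"TFR ratio undefined: female TFR is 0 in {female.year}")
    mac_m, mac_f = mac(male), mac(female)
    return SummaryIndicators(
        year=male.year,
        male_tfr=male_tfr,
        female_tfr=female_tfr,
        tfr_ratio=male_tfr / female_tfr,
        mac_male=mac_m,
        mac_female=mac_f,
        mac_difference=mac_m - mac_f,
    )


def cohort_compare(
    male_schedules: Mapping[int, ASFRSchedule],
    female_schedules: Mapping[int, ASFRSchedule],
    cohort: int,
) -> tuple[float, float, float]:
    """(male CFR, female CFR, CFR ratio) for one birth cohort."""
    cfr_m = cfr(male_schedules, cohort)
    cfr_f = cfr(female_schedules, cohort)
    if cfr_f <= 0:
        raise DataError(f"CFR ratio undefined: female CFR is 0 for cohort {cohort}")
    return cfr_m, cfr_f, cfr_m / cfr_f
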