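"""Synthetic two-sex birth registers with known ground truth.

The generator is female-dominant: a parametric female fertility schedule
drives expected births, and each birth is assigned a paternal age equal to
the maternal age plus a draw from a discrete parental age-gap distribution.
This mirrors how male rates are obtained in register-based practice (derived
from births, never modelled structurally) and keeps the ground-truth
indicators analytic.

Mechanisms emulated: a gamma-shaped female schedule with an optional
postponement drift, cohort-size variation (boom/bust), a sex ratio at birth
around 105 males per 100 females, optional sex-differential survival, and a
paternal-age missingness mechanism (MCAR / MAR on maternal age / MNAR on
paternal age).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .tables import (
    FEMALE_AGES,
    MALE_AGE_MAX,
    MALE_AGE_MIN,
    MALE_AGES,
    UNKNOWN,
    BirthTable,
    ConfigurationError,
    ExposureTable,
)

if TYPE_CHECKING:
    from .tables import SummaryIndicators

#: integer support of the parental age-gap distribution (father - mother)
GAP_MIN, GAP_MAX = -10, 25

MISSING_MODELS = ("MCAR", "MAR_maternal_age", "MNAR_paternal_age")

#: maternal reference age at which base rates / gap means are anchored
REFERENCE_AGE = 30


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic register scenario.

    Parameters
    ----------
    years
        Inclusive calendar-year range ``(first, last)``.
    srb
        Sex ratio at birth, males per 100 females.
    cohort_sizes
        Female cohort size per birth year; a scalar means every cohort has
        that size. Male cohorts are ``female size x srb/100``.
    quantum
        Target female period TFR (children per woman).
    mean_age, spread
        Mean and standard deviation (years) of the gamma-shaped female
        fertility schedule in the first year.
    postponement
        Drift of the schedule's mean age, in years per calendar year.
    gap_mean, gap_sd
        Mean and standard deviation of the parental age gap
        (paternal age - maternal age), discretized on -10..+25.
    gap_trend
        Drift of the mean gap per calendar year.
    gap_age_slope
        Change in the mean gap per year of maternal age (anchored at
        maternal age 30); lets the father-age distribution depend on the
        mother's age beyond truncation.
    missing_model
        ``None`` (complete data) or one of MCAR, MAR_maternal_age,
        MNAR_paternal_age.
    missing_base
        Probability that the paternal age is missing at the reference
        parental age of 30.
    missing_slope
        Log-odds change of missingness per year of (maternal or paternal)
        age for the MAR/MNAR mechanisms.
    survival
        Optional per-sex cumulative survival/migration factors by age,
        e.g. ``{"male": {age: factor}}``; missing entries default to 1.
    poisson_noise
        If True, cell counts are Poisson draws; otherwise expectations.
    seed
        Master seed; stochastic stages derive their streams from it.
    """

    years: tuple[int, int]
    srb: float = 105.0
    cohort_sizes: float | Mapping[int, float] = 100_000.0
    quantum: float = 1.8
    mean_age: float = 29.0
    spread: float = 4.5
    postponement: float = 0.0
    gap_mean: float = 3.0
    gap_sd: float = 2.0
    gap_trend: float = 0.0
    gap_age_slope: float = 0.0
    missing_model: str | None = None
    missing_base: float = 0.0
    missing_slope: float = 0.0
    survival: Mapping[str, Mapping[int, float]] | None = None
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = int(self.years[0]), int(self.years[1])
        if y1 < y0:
            raise ConfigurationError(f"empty year range {self.years}")
        self.years = (y0, y1)
        if self.srb <= 0:
            raise ConfigurationError("srb must be positive")
        if self.quantum <= 0:
            raise ConfigurationError("quantum must be positive")
        if self.spread <= 0:
            raise ConfigurationError("spread must be positive")
        if self.gap_sd < 0:
            raise ConfigurationError("gap_sd must be non-negative")
        if not (0.0 <= self.missing_base < 1.0):
            raise ConfigurationError("base missing rate must lie in [0, 1)")
        if self.missing_model is not None:
            if self.missing_model not in MISSING_MODELS:
                raise ConfigurationError(
                    f"missing_model must be one of {MISSING_MODELS}"
                )
            if self.missing_slope != 0.0 and self.missing_base == 0.0:
                raise ConfigurationError(
                    "a missingness slope requires a positive base rate"
                )
        if isinstance(self.cohort_sizes, Mapping):
            if any(v <= 0 for v in self.cohort_sizes.values()):
                raise ConfigurationError("cohort sizes must be strictly positive")
        elif self.cohort_sizes <= 0:
            raise ConfigurationError("cohort sizes must be strictly positive")

    # -- derived quantities -------------------------------------------------

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def cohort_size(self, cohort: int) -> float:
        if isinstance(self.cohort_sizes, Mapping):
            try:
                return float(self.cohort_sizes[cohort])
            except KeyError:
                raise ConfigurationError(
                    f"cohort {cohort} has no configured size"
                ) from None
        return float(self.cohort_sizes)

    def survival_factor(self, sex: str, age: int) -> float:
        if self.survival is None:
            return 1.0
        return float(self.survival.get(sex, {}).get(age, 1.0))

    def female_asfr(self, year: int) -> pd.Series:
        """The configured female schedule for one year (sums to quantum)."""
        mean = self.mean_age + self.postponement * (year - self.years[0])
        # gamma on x = age + 0.5 - 15 matched to (mean, spread) by moments
        x = FEMALE_AGES + 0.5 - 15.0
        mu = mean - 15.0
        if mu <= 0:
            raise ConfigurationError(f"schedule mean age {mean} below age 15")
        shape = (mu / self.spread) ** 2
        scale = self.spread**2 / mu
        w = stats.gamma.pdf(x, a=shape, scale=scale)
        total = w.sum()
        if total <= 0:
            raise ConfigurationError("degenerate fertility schedule")
        return pd.Series(self.quantum * w / total, index=FEMALE_AGES)

    def gap_probabilities(self, year: int, mother_age: int) -> pd.Series:
        """Discretized, truncated age-gap distribution for one mother age.

        Support is the integers of ``GAP_MIN..GAP_MAX`` whose implied
        paternal age lies in 15-59; probabilities renormalized.
        """
        gaps = np.arange(GAP_MIN, GAP_MAX + 1)
        keep = (mother_age + gaps >= MALE_AGE_MIN) & (
            mother_age + gaps <= MALE_AGE_MAX
        )
        gaps = gaps[keep]
        mean = (
            self.gap_mean
            + self.gap_trend * (year - self.years[0])
            + self.gap_age_slope * (mother_age - REFERENCE_AGE)
        )
        if self.gap_sd == 0.0:
            target = int(round(mean))
            p = (gaps == target).astype(float)
            if p.sum() == 0:
                # degenerate gap pushed outside the male age range: clamp
                target = int(np.clip(target, gaps.min(), gaps.max()))
                p = (gaps == target).astype(float)
        else:
            p = stats.norm.pdf(gaps, loc=mean, scale=self.gap_sd)
        return pd.Series(p / p.sum(), index=gaps)

    def missing_probability(self, mother_age: int, father_age: int) -> float:
        """Probability that a birth's paternal age goes unrecorded."""
        if self.missing_model is None or self.missing_base == 0.0:
            return 0.0
        if self.missing_model == "MCAR":
            return self.missing_base
        if self.missing_model == "MAR_maternal_age":
            z = logit(self.missing_base) + self.missing_slope * (
                mother_age - REFERENCE_AGE
            )
        else:  # MNAR_paternal_age
            z = logit(self.missing_base) + self.missing_slope * (
                father_age - REFERENCE_AGE
            )
        return float(expit(z))

    def rng(self, stage: int) -> np.random.Generator:
        """Stream for one stochastic stage (0=births, 1=missingness)."""
        return np.random.default_rng([int(self.seed), int(stage)])


# -- generation --------------------------------------------------------------


def generate_exposures(config: ScenarioConfig) -> ExposureTable:
    """Person-years by sex, age and year implied by the cohort sizes.

    exposure(sex, age, year) = female size of cohort (year - age), times the
    sex share (1 for women, srb/100 for men), times the survival factor.
    Deterministic given the configuration.
    """
    rows = []
    srb_factor = config.srb / 100.0
    for year in config.year_list():
        for sex, ages in (("female", FEMALE_AGES), ("male", MALE_AGES)):
            share = srb_factor if sex == "male" else 1.0
            for age in ages:
                size = config.cohort_size(year - int(age))
                rows.append(
                    (
                        sex,
                        int(age),
                        year,
                        size * share * config.survival_factor(sex, int(age)),
                    )
                )
    return ExposureTable(pd.DataFrame(rows, columns=["sex", "age", "year", "exposure"]))


def generate_births(config: ScenarioConfig, exposures: ExposureTable) -> BirthTable:
    """Birth counts by (year, maternal age, paternal age); no unknown ages.

    Expected births at (year, m) are female exposure times the configured
    female ASFR; each birth's paternal age is m plus a draw from the
    discretized gap distribution. With ``poisson_noise`` the cell counts are
    independent Poisson draws; otherwise they are the exact expectations.
    """
    rng = config.rng(0) if config.poisson_noise else None
    rows = []
    for year in config.year_list():
        asfr = config.female_asfr(year)
        exp_f = exposures.series("female", year)
        if exp_f.isna().any():
            missing = list(exp_f.index[exp_f.isna()])
            raise ConfigurationError(
                f"female exposure missing for ages {missing} in {year}"
            )
        for m in FEMALE_AGES:
            expected = exp_f[m] * asfr[m]
            if expected == 0:
                continue
            probs = config.gap_probabilities(year, int(m))
            for gap, p in probs.items():
                if p == 0:
                    continue
                cell = expected * p
                if rng is not None:
                    cell = float(rng.poisson(cell))
                if cell > 0:
                    rows.append((year, int(m), int(m) + int(gap), cell))
    return BirthTable(pd.DataFrame(rows, columns=["year", "mother_age", "father_age", "count"]))


def apply_missingness(births: BirthTable, config: ScenarioConfig) -> BirthTable:
    """Move a fraction of each cell to paternal age unknown.

    MCAR: constant fraction. MAR_maternal_age: fraction logistic in maternal
    age. MNAR_paternal_age: logistic in paternal age. Per-year totals are
    untouched. In expectation mode the moved amounts are exact fractions; in
    Poisson-noise mode they are binomial draws so counts stay integer.
    """
    if births.has_unknown_father():
        raise ConfigurationError("births already contain unknown paternal ages")
    if config.missing_model is None or config.missing_base == 0.0:
        return births.copy()
    rng = config.rng(1) if config.poisson_noise else None
    df = births.df.copy()
    moved = np.zeros(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        q = config.missing_probability(row.mother_age, row.father_age)
        if q == 0.0:
            continue
        if rng is not None:
            moved[i] = rng.binomial(int(round(row.count)), q)
        else:
            moved[i] = row.count * q
    out = df.copy()
    out["count"] = df["count"] - moved
    unk = df.assign(count=moved, father_age=UNKNOWN)
    unk = unk[unk["count"] > 0]
    return BirthTable(pd.concat([out[out["count"] > 0], unk], ignore_index=True))


def true_indicators(
    births: BirthTable, exposures: ExposureTable
) -> dict[int, "SummaryIndicators"]:
    """Ground-truth indicators per year from a complete birth table.

    Computed through the rates module on the table *before* any missingness,
    so recovery tests can compare imputed results against them.
    """
    from .rates import compare, compute_asfr

    if births.has_unknown_father() or births.has_unknown_mother():
        raise ConfigurationError("true_indicators requires a complete table")
    out = {}
    for year in births.years():
        male = compute_asfr(births, exposures, "male", year)
        female = compute_asfr(births, exposures, "female", year)
        out[year] = compare(male, female)
    return out
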