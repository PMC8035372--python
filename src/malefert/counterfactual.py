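"""Same-age counterfactual and decomposition of TFR-ratio differentials.

The counterfactual erases the paternal age of every birth and assumes each
father is exactly as old as the mother. Rates computed with male exposures
under that assumption remove the contribution of parental age gaps and
differential birth timing; what remains of the male/female TFR difference is
attributable to imbalanced sex ratios. A reference ratio of 100/srb (about
0.952 at the usual 105:100 sex ratio at birth) marks the level expected from
the sex ratio at birth alone, with no sex-selective mortality or migration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import (
    FEMALE_AGES,
    ASFRSchedule,
    BirthTable,
    DataError,
    ExposureTable,
    age_support,
)
from .rates import compute_asfr, tfr


@dataclass
class CounterfactualResult:
    """Counterfactual male schedule and TFR ratio for one year."""

    year: int
    male_schedule: ASFRSchedule  # counterfactual; zero above age 49
    male_tfr: float
    female_tfr: float
    ratio: float


def same_age_counterfactual(
    births: BirthTable, exposures: ExposureTable, year: int | None = None
) -> CounterfactualResult:
    """Male TFR ratio assuming every father has the mother's age.

    Counterfactual male births at age x are the births with maternal age x
    (paternal ages are never read); counterfactual male rates divide them by
    the observed male exposures at ages 15-49. The ratio divides the
    counterfactual male TFR by the observed female TFR. Fathers inherit
    maternal ages, so no counterfactual births occur at ages 50-59 and the
    schedule is zero there.
    """
    if year is None:
        years = births.years()
        if len(years) != 1:
            raise ValueError("year must be given for a multi-year table")
        year = years[0]
    by_mother = births.births_by_age("female", year)  # errors if mother unknown
    exp_m = exposures.series("male", year)
    needed = exp_m.loc[FEMALE_AGES]
    if needed.isna().any():
        missing = list(needed.index[needed.isna()])
        raise DataError(f"male exposure missing for ages {missing} in {year}")
    if ((needed <= 0) & (by_mother > 0)).any():
        raise DataError(f"births with zero male exposure in {year}")
    rates = pd.Series(0.0, index=age_support("male"))
    pos = needed > 0
    rates.loc[needed.index[pos]] = by_mother[pos] / needed[pos]
    cf_schedule = ASFRSchedule("male", int(year), rates)
    cf_tfr = tfr(cf_schedule)
    female_tfr = tfr(compute_asfr(births, exposures, "female", year))
    if female_tfr <= 0:
        raise DataError(f"counterfactual ratio undefined: female TFR 0 in {year}")
    return CounterfactualResult(int(year), cf_schedule, cf_tfr, female_tfr, cf_tfr / female_tfr)


def reference_ratio(srb: float) -> float:
    """TFR ratio implied by the sex ratio at birth alone: 100 / srb.

    ``srb`` is males per 100 females; with srb=105 the reference is
    100/105, about 0.952 — the level expected with no sex-selective
    mortality or migration over the reproductive lifespan.
    """
    if srb <= 0:
        raise ValueError("srb must be positive")
    return 100.0 / srb


@dataclass
class Decomposition:
    """Additive split of the observed TFR ratio's departure from 1.

    timing_age_gap: observed - counterfactual (parental age gaps x cohort
    size variation, plus differential timing). mortality_migration_residual:
    counterfactual - reference (sex-selective survival/migration and any
    residual; exact attribution to the sex ratio at birth holds only absent
    those). srb_component: reference - 1. Components sum to observed - 1.
    """

    observed: float
    counterfactual: float
    reference: float
    timing_age_gap: float
    mortality_migration_residual: float
    srb_component: float

    @property
    def total(self) -> float:
        return self.observed - 1.0

    def as_dict(self) -> dict[str, float]:
        return {
            "observed": self.observed,
            "counterfactual": self.counterfactual,
            "reference": self.reference,
            "timing_age_gap": self.timing_age_gap,
            "mortality_migration_residual": self.mortality_migration_residual,
            "srb_component": self.srb_component,
            "total": self.total,
        }


def decompose(observed: float, counterfactual: float, reference: float) -> Decomposition:
    """Decompose observed ratio - 1 into three labeled components."""
    return Decomposition(
        observed=observed,
        counterfactual=counterfactual,
        reference=reference,
        timing_age_gap=observed - counterfactual,
        mortality_migration_residual=counterfactual - reference,
        srb_component=reference - 1.0,
    )
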