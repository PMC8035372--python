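"""Readers/writers for the package's table dialects and the pipeline driver.

Dialects
--------
* births, tidy CSV: columns ``Year,MotherAge,FatherAge,Count`` with ``UNK``
  for unknown ages.
* births, matrix CSV: one calendar year; maternal ages as rows, paternal
  ages as columns, each margin optionally carrying an ``UNK`` row/column.
* exposures CSV: ``Sex,Age,Year,Exposure``.
* grouped counts CSV: ``AgeLow,Width,Count`` with ``Width=open`` for a final
  open-ended interval.
* ASFR, HFC-style whitespace-delimited text: ``Country Year Age ASFR`` with
  rates to 6 decimals, rows sorted by (Year, Age).
* scenario config: flat TOML; ``cohort_size`` (scalar) or a
  ``[cohort_sizes]`` table keyed by birth year.
"""

from __future__ import annotations

import logging
import tomllib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import (
    UNK_TOKEN,
    UNKNOWN,
    ASFRSchedule,
    BirthTable,
    ExposureTable,
    ParseError,
    age_support,
)
from .synthetic import ScenarioConfig
from .age_interval import GroupedCounts

log = logging.getLogger("malefert")


def _parse_age(token: str, path: Path, line: int) -> int:
    token = str(token).strip()
    if token == UNK_TOKEN:
        return UNKNOWN
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{line}: malformed age {token!r}") from None


# -- birth tables ------------------------------------------------------------


def read_birth_table(path: str | Path, dialect: str = "tidy", year: int | None = None) -> BirthTable:
    """Read a birth table; ``dialect`` is 'tidy' or 'matrix'.

    The matrix dialect holds a single year (maternal rows x paternal
    columns) and therefore requires ``year``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    if dialect == "tidy":
        return _read_tidy(path)
    if dialect == "matrix":
        if year is None:
            raise ValueError("the matrix dialect requires year=")
        return _read_matrix(path, year)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tidy(path: Path) -> BirthTable:
    df = pd.read_csv(path, dtype=str)
    expected = ["Year", "MotherAge", "FatherAge", "Count"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}:1: expected header {','.join(expected)}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count = float(row.Count)
        except ValueError:
            raise ParseError(f"{path}:{i}: malformed count {row.Count!r}") from None
        if count < 0:
            raise ParseError(f"{path}:{i}: negative count {count:g}")
        rows.append(
            (
                int(row.Year),
                _parse_age(row.MotherAge, path, i),
                _parse_age(row.FatherAge, path, i),
                count,
            )
        )
    return BirthTable.from_records(rows)


def _read_matrix(path: Path, year: int) -> BirthTable:
    df = pd.read_csv(path, index_col=0)
    rows = []
    for i, (m_tok, row) in enumerate(df.iterrows(), start=2):
        m = _parse_age(str(m_tok), path, i)
        for p_tok, count in row.items():
            p = _parse_age(str(p_tok), path, i)
            count = float(count)
            if count < 0:
                raise ParseError(f"{path}:{i}: negative count {count:g}")
            if count > 0:
                rows.append((year, m, p, count))
    if not rows:
        raise ParseError(f"{path}: no positive counts")
    return BirthTable.from_records(rows)


def write_birth_table(births: BirthTable, path: str | Path) -> None:
    """Write the tidy CSV dialect."""
    df = births.df.copy()
    for col in ("mother_age", "father_age"):
        df[col] = df[col].map(lambda a: UNK_TOKEN if a == UNKNOWN else str(a))
    df.columns = ["Year", "MotherAge", "FatherAge", "Count"]
    df.to_csv(path, index=False)


# -- exposures ---------------------------------------------------------------


def read_exposure_table(path: str | Path) -> ExposureTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    df = pd.read_csv(path)
    expected = ["Sex", "Age", "Year", "Exposure"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}:1: expected header {','.join(expected)}")
    df.columns = ["sex", "age", "year", "exposure"]
    df["sex"] = df["sex"].str.lower()
    return ExposureTable(df)


def write_exposure_table(exposures: ExposureTable, path: str | Path) -> None:
    df = exposures.df.copy()
    df.columns = ["Sex", "Age", "Year", "Exposure"]
    df.to_csv(path, index=False)


# -- grouped counts ----------------------------------------------------------


def read_grouped_counts(path: str | Path, grid: Iterable[int]) -> GroupedCounts:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["AgeLow", "Width", "Count"]:
        raise ParseError(f"{path}:1: expected header AgeLow,Width,Count")
    intervals, counts = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        width = None if str(row.Width).strip() == "open" else int(row.Width)
        intervals.append((int(row.AgeLow), width))
        counts.append(float(row.Count))
    return GroupedCounts(intervals, np.array(counts), np.array(list(grid)))


def write_grouped_counts(grouped: GroupedCounts, path: str | Path) -> None:
    rows = [
        (low, "open" if width is None else width, count)
        for (low, width), count in zip(grouped.intervals, grouped.counts)
    ]
    pd.DataFrame(rows, columns=["AgeLow", "Width", "Count"]).to_csv(path, index=False)


# -- HFC-style ASFR files ----------------------------------------------------


def write_asfr_hfc(
    schedules: Iterable[ASFRSchedule], path: str | Path, country: str = "SYN"
) -> None:
    """Whitespace-delimited ``Country Year Age ASFR`` rows, 6-decimal rates,
    sorted by (Year, Age)."""
    rows = []
    for sched in schedules:
        for age, rate in sched.rates.items():
            rows.append((country, sched.year, int(age), rate))
    rows.sort(key=lambda r: (r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("Country Year Age ASFR\n")
        for country_, year, age, rate in rows:
            fh.write(f"{country_} {year} {age} {rate:.6f}\n")


def read_asfr_hfc(path: str | Path, sex: str) -> dict[int, ASFRSchedule]:
    """Read back HFC-style rates into per-year schedules for one sex."""
    df = pd.read_csv(path, sep=r"\s+")
    out = {}
    for year, sub in df.groupby("Year"):
        rates = sub.set_index("Age")["ASFR"].reindex(age_support(sex), fill_value=0.0)
        out[int(year)] = ASFRSchedule(sex, int(year), rates)
    return out


# -- scenario config ---------------------------------------------------------


def load_scenario_config(path: str | Path, seed: int | None = None) -> ScenarioConfig:
    """Load a ScenarioConfig from flat TOML; ``seed`` overrides the file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cohort_sizes: float | Mapping[int, float]
    if "cohort_sizes" in raw:
        cohort_sizes = {int(k): float(v) for k, v in raw.pop("cohort_sizes").items()}
    else:
        cohort_sizes = float(raw.pop("cohort_size", 100_000.0))
    survival = raw.pop("survival", None)
    if survival is not None:
        survival = {
            sex: {int(a): float(f) for a, f in table.items()}
            for sex, table in survival.items()
        }
    years = tuple(raw.pop("years"))
    if seed is not None:
        raw["seed"] = seed
    return ScenarioConfig(years=years, cohort_sizes=cohort_sizes, survival=survival, **raw)
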