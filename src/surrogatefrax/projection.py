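"""National fracture-burden estimation and projection.

Applies fixed age/sex-specific incidence to population pyramids: each
projection year is an independent cross-sectional product of the rates and
that year's pyramid (no cohort dynamics — the "incidence remains stable"
assumption).  Expected counts are kept real-valued internally; reports
round to whole fractures and percent increases round half-up to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from surrogatefrax.errors import AgeRangeError, AlignmentError
from surrogatefrax.tables import SEXES, IncidenceTable, PopulationTable

DEFAULT_YEARS = (2015, 2020, 2030, 2040, 2050)
DEFAULT_MIN_AGE = 50


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going away from zero."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def expected_counts(
    incidence: IncidenceTable,
    population: PopulationTable,
    year: int,
    min_age: int = DEFAULT_MIN_AGE,
) -> dict[str, float]:
    """Expected annual fracture count per sex for one calendar year.

    Sums rate/100,000 x persons over every population band whose lower edge
    is at least ``min_age``; bands starting below ``min_age`` are excluded
    entirely.  Incidence and population must share band edges for the bands
    used — there is no proration across mismatched bands.
    """
    if year not in population.years:
        raise AgeRangeError(f"population table has no year {year}")
    counts = {sex: 0.0 for sex in SEXES}
    for sex, band in population.cells():
        if band.lo < min_age:
            continue
        persons = population.count(year, sex, band)
        try:
            rate = incidence.entries[(sex, band)]
        except KeyError:
            raise AlignmentError(
                f"incidence table has no band {band} for sex {sex} "
                "matching the population band (no proration)"
            ) from None
        counts[sex] += rate / 100_000.0 * persons
    return counts


@dataclass(frozen=True)
class ProjectionResult:
    """Projected fracture counts by sex and year, with percent increases.

    ``pct_increase`` holds the unrounded percent change of each year's
    total versus the base year; ``pct_increase_rounded`` the half-up
    integer a report would print.  The base year's increase is 0.
    """

    counts: Mapping[tuple[int, str], float]
    totals: Mapping[int, float]
    pct_increase: Mapping[int, float]
    pct_increase_rounded: Mapping[int, int]
    base_year: int

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.totals))

    def to_frame(self) -> pd.DataFrame:
        """Report table: rows Men/Women/Total/Increase (%) x year columns.

        Counts are rounded to whole fractures for presentation; the
        increase row shows the half-up integer percent (blank for the
        base year).
        """
        years = self.years
        rows = {
            "Men": [round_half_up(self.counts[(y, "M")]) for y in years],
            "Women": [round_half_up(self.counts[(y, "F")]) for y in years],
            "Total": [round_half_up(self.totals[y]) for y in years],
            "Increase (%)": [
                "-" if y == self.base_year else self.pct_increase_rounded[y]
                for y in years
            ],
        }
        return pd.DataFrame(rows, index=[str(y) for y in years]).T


def project(
    incidence: IncidenceTable,
    population: PopulationTable,
    years: Sequence[int] = DEFAULT_YEARS,
    base_year: int = 2015,
    min_age: int = DEFAULT_MIN_AGE,
) -> ProjectionResult:
    """Project expected fracture counts over calendar years.

    Every requested year (and the base year) must be present in the
    population table.  Percent increases are relative to the base year's
    total.
    """
    if base_year not in population.years:
        raise AgeRangeError(f"population table has no base year {base_year}")
    all_years = sorted(set(years) | {base_year})
    counts: dict[tuple[int, str], float] = {}
    totals: dict[int, float] = {}
    for year in all_years:
        by_sex = expected_counts(incidence, population, year, min_age=min_age)
        for sex, c in by_sex.items():
            counts[(year, sex)] = c
        totals[year] = sum(by_sex.values())
    base_total = totals[base_year]
    pct: dict[int, float] = {}
    for year in all_years:
        if base_total == 0.0:
            pct[year] = 0.0 if totals[year] == 0.0 else float("inf")
        else:
            pct[year] = 100.0 * (totals[year] - base_total) / base_total
    rounded = {
        y: round_half_up(p) if math.isfinite(p) else p for y, p in pct.items()
    }
    return ProjectionResult(
        counts=counts,
        totals=totals,
        pct_increase=pct,
        pct_increase_rounded=rounded,
        base_year=base_year,
    )
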