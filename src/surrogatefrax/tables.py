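"""Epidemiological rate and population tables.

All rate tables are banded by sex and half-open integer age intervals
[lo, hi).  Hip-fracture incidence is stored as events per 100,000
person-years (the convention registries publish in); mortality as annual
deaths per person-year; MOF:hip ratios are unitless.  A final band may be
open-ended (``age_hi`` empty in CSV, ``None`` in memory) and is treated as
extending to a hard model ceiling of age :data:`AGE_CEILING`.  Within a band
the hazard is constant — single-year expansion never interpolates, matching
abridged-life-table practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from surrogatefrax.errors import (
    AgeRangeError,
    AlignmentError,
    SchemaError,
    ValidationError,
)

#: Hard upper bound of the model's age axis; an open-ended final band is
#: read as [lo, AGE_CEILING).
AGE_CEILING = 100

#: Minimum age interval each sex's bands must cover.
REQUIRED_COVERAGE = (50, 90)

SEXES = ("M", "F")

_RATE_COLUMNS = ["sex", "age_lo", "age_hi", "value"]
_POP_COLUMNS = ["year", "sex", "age_lo", "age_hi", "count"]


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open integer age interval [lo, hi); ``hi=None`` means open-ended."""

    lo: int
    hi: int | None

    def __post_init__(self) -> None:
        if self.hi is not None and self.hi <= self.lo:
            raise ValidationError(f"empty or inverted age band [{self.lo}, {self.hi})")

    @property
    def upper(self) -> int:
        """Effective exclusive upper edge (ceiling-capped)."""
        return AGE_CEILING if self.hi is None else self.hi

    def contains(self, age: int) -> bool:
        return self.lo <= age < self.upper

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.upper)

    def __str__(self) -> str:
        hi = "" if self.hi is None else self.hi
        return f"[{self.lo},{hi})"


def _validate_bands(sex: str, bands: Sequence[AgeBand]) -> None:
    ordered = sorted(bands)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi is None:
            raise ValidationError(f"sex {sex}: open-ended band {a} is not last")
        if a.hi != b.lo:
            kind = "overlap" if a.hi > b.lo else "gap"
            raise ValidationError(f"sex {sex}: band {kind} between {a} and {b}")
    lo_cov, hi_cov = REQUIRED_COVERAGE
    if ordered[0].lo > lo_cov or ordered[-1].upper < hi_cov:
        raise ValidationError(
            f"sex {sex}: bands cover [{ordered[0].lo}, {ordered[-1].upper}) "
            f"but must cover at least [{lo_cov}, {hi_cov})"
        )


class BandedTable:
    """Base container: map of (sex, band) -> value with validated banding."""

    #: lower bound admissible for values; subclasses may tighten
    _min_value = 0.0
    _value_name = "rate"

    def __init__(
        self,
        entries: Mapping[tuple[str, AgeBand], float]
        | Iterable[tuple[str, int, int | None, float]],
        country_label: str = "",
    ) -> None:
        if isinstance(entries, Mapping):
            items = [(s, b, v) for (s, b), v in entries.items()]
        else:
            items = [(s, AgeBand(lo, hi), v) for s, lo, hi, v in entries]
        self.entries: dict[tuple[str, AgeBand], float] = {}
        for sex, band, value in items:
            if sex not in SEXES:
                raise ValidationError(f"unknown sex code {sex!r} (expected M or F)")
            value = float(value)
            if not math.isfinite(value) or value < self._min_value:
                raise ValidationError(
                    f"{self._value_name} {value} for sex {sex} band {band} "
                    f"must be finite and >= {self._min_value}"
                )
            key = (sex, band)
            if key in self.entries:
                raise ValidationError(f"duplicate band {band} for sex {sex}")
            self.entries[key] = value
        self.country_label = country_label
        by_sex: dict[str, list[AgeBand]] = {}
        for sex, band in self.entries:
            by_sex.setdefault(sex, []).append(band)
        if not by_sex:
            raise ValidationError("table has no entries")
        for sex, bands in by_sex.items():
            _validate_bands(sex, bands)
        self._bands_by_sex = {s: tuple(sorted(b)) for s, b in by_sex.items()}

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(s for s in SEXES if s in self._bands_by_sex)

    def bands(self, sex: str) -> tuple[AgeBand, ...]:
        try:
            return self._bands_by_sex[sex]
        except KeyError:
            raise AgeRangeError(f"no bands for sex {sex!r}") from None

    def band_for(self, sex: str, age: int) -> AgeBand:
        for band in self.bands(sex):
            if band.contains(age):
                return band
        lo = self.bands(sex)[0].lo
        hi = self.bands(sex)[-1].upper
        raise AgeRangeError(
            f"age {age} outside coverage [{lo}, {hi}) for sex {sex}"
        )

    def value_at(self, sex: str, age: int) -> float:
        """Raw band value at an exact integer age (no unit conversion)."""
        return self.entries[(sex, self.band_for(sex, age))]

    def age_span(self, sex: str) -> tuple[int, int]:
        """Covered [lo, hi) for one sex, ceiling applied."""
        bands = self.bands(sex)
        return bands[0].lo, bands[-1].upper

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "age_lo": b.lo, "age_hi": b.hi, "value": v}
            for (s, b), v in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1])
            )
        ]
        return pd.DataFrame(rows, columns=_RATE_COLUMNS)

    def same_bands_as(self, other: "BandedTable") -> bool:
        return self._bands_by_sex == other._bands_by_sex

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, type(self))
            and self.entries == other.entries
            and self.country_label == other.country_label
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}({len(self.entries)} bands, "
            f"label={self.country_label!r})"
        )


class IncidenceTable(BandedTable):
    """Fracture incidence, events per 100,000 person-years per (sex, band)."""

    _value_name = "incidence rate"


class MortalityTable(BandedTable):
    """All-cause annual death hazard per person-year per (sex, band)."""

    _value_name = "mortality rate"


class RatioTable(BandedTable):
    """MOF:hip incidence ratio per (sex, band); MOF includes hip, so >= 1."""

    _min_value = 1.0
    _value_name = "MOF:hip ratio"


class PopulationTable:
    """Person counts by (year, sex, band); every (sex, band) cell present per year."""

    def __init__(
        self, entries: Iterable[tuple[int, str, int, int | None, float]]
    ) -> None:
        self.entries: dict[tuple[int, str, AgeBand], float] = {}
        for year, sex, lo, hi, count in entries:
            if sex not in SEXES:
                raise ValidationError(f"unknown sex code {sex!r}")
            count = float(count)
            if not math.isfinite(count) or count < 0:
                raise ValidationError(f"negative population count {count}")
            key = (int(year), sex, AgeBand(lo, hi))
            if key in self.entries:
                raise ValidationError(f"duplicate population cell {key}")
            self.entries[key] = count
        if not self.entries:
            raise ValidationError("population table has no entries")
        cells_by_year: dict[int, set[tuple[str, AgeBand]]] = {}
        for year, sex, band in self.entries:
            cells_by_year.setdefault(year, set()).add((sex, band))
        cells = iter(cells_by_year.values())
        first = next(cells)
        for other in cells:
            if other != first:
                raise ValidationError(
                    "population years do not share the same (sex, band) cells"
                )
        self.years = tuple(sorted(cells_by_year))
        self._cells = tuple(sorted(first))

    def cells(self) -> tuple[tuple[str, AgeBand], ...]:
        return self._cells

    def count(self, year: int, sex: str, band: AgeBand) -> float:
        try:
            return self.entries[(year, sex, band)]
        except KeyError:
            raise AgeRangeError(
                f"no population cell for year={year}, sex={sex}, band={band}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "sex": s, "age_lo": b.lo, "age_hi": b.hi, "count": c}
            for (y, s, b), c in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            )
        ]
        return pd.DataFrame(rows, columns=_POP_COLUMNS)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PopulationTable) and self.entries == other.entries


_SCHEMAS = {
    "incidence": IncidenceTable,
    "mortality": MortalityTable,
    "ratio": RatioTable,
    "population": PopulationTable,
}


def _parse_hi(raw) -> int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    return int(raw)


def read_table(path: str | Path, schema: str):
    """Read a validated table from CSV.

    Parameters
    ----------
    path : file path to a UTF-8 CSV with a header row.
    schema : one of ``incidence``, ``mortality``, ``ratio``, ``population``.

    Rate schemas use columns ``sex, age_lo, age_hi, value`` (empty ``age_hi``
    = open-ended band); population uses ``year, sex, age_lo, age_hi, count``.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, dtype={"sex": str})
    required = _POP_COLUMNS if schema == "population" else _RATE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema!r}")
    if schema == "population":
        return PopulationTable(
            (int(r.year), r.sex, int(r.age_lo), _parse_hi(r.age_hi), r.count)
            for r in df.itertuples()
        )
    return _SCHEMAS[schema](
        ((r.sex, int(r.age_lo), _parse_hi(r.age_hi), r.value) for r in df.itertuples()),
    )


def write_table(table, path: str | Path) -> None:
    """Write a table to CSV so that ``read_table`` round-trips it."""
    df = table.to_frame()
    hi = df["age_hi"]
    df["age_hi"] = hi.map(
        lambda v: ""
        if v is None or (isinstance(v, float) and math.isnan(v))
        else str(int(v))
    )
    df.to_csv(path, index=False)


def hazard_at(table: IncidenceTable | MortalityTable, sex: str, age: int) -> float:
    """Per-person-year hazard at one integer age.

    Incidence rates are converted from per-100,000-person-years; mortality
    rates pass through unchanged.  Piecewise constant within each band;
    no extrapolation outside coverage (raises :class:`AgeRangeError`).
    """
    value = table.value_at(sex, age)
    if isinstance(table, IncidenceTable):
        return value / 100_000.0
    return value


def require_aligned(a: BandedTable, b: BandedTable, what: str) -> None:
    """Raise AlignmentError unless both tables share identical band edges per sex."""
    if not a.same_bands_as(b):
        raise AlignmentError(f"{what}: band structures differ between tables")
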