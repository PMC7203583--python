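"""Synthetic epidemiological tables and the Monte-Carlo cohort oracle.

Real hip-fracture incidence and national mortality both rise roughly
exponentially with adult age, so the generators use Gompertz-like band
rates ``alpha * exp(beta * (midpoint - 50))`` with known parameters: every
pipeline stage can be exercised against closed forms and parameter-recovery
checks without any external data.  The default scenario produces a
moderate-risk source country ("authentic") and a target country that
differs only in mortality, mirroring the surrogate-model construction.

``simulate_cohort`` is an independent stochastic check on the probability
engine: it draws individual life courses with exactly the engine's
piecewise-constant hazards (a single exponential total-hazard draw per
year, plus a Bernoulli cause split h_f/(h_f+h_d)), so engine and simulation
estimate the same quantity and differ only by binomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import math

import numpy as np

from surrogatefrax.engine import (
    FraxModel,
    RiskProfile,
    default_relative_risks,
    relative_risk,
)
from surrogatefrax.errors import ConfigurationError, ValidationError
from surrogatefrax.tables import (
    AgeBand,
    IncidenceTable,
    MortalityTable,
    PopulationTable,
    RatioTable,
    hazard_at,
)


@dataclass(frozen=True)
class GompertzParams:
    """Exponential age structure: rate(age) = alpha * exp(beta * (age - 50)).

    ``alpha`` is the rate at age 50 in whatever unit the target table uses
    (per 100,000 person-years for incidence, per person-year for
    mortality); ``beta`` is the log-slope per year of age.
    """

    alpha: float
    beta: float
    sex: str

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValidationError("alpha must be > 0")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


def default_bands(lo: int = 50, hi: int = 95, width: int = 5) -> tuple[AgeBand, ...]:
    """5-year bands [50,55) .. [90,95) plus an open-ended final band."""
    bands = [AgeBand(a, a + width) for a in range(lo, hi, width)]
    bands.append(AgeBand(hi, None))
    return tuple(bands)


def _gompertz_rates(params: GompertzParams, bands: Sequence[AgeBand]):
    for band in bands:
        yield band, params.alpha * math.exp(params.beta * (band.midpoint - 50.0))


def synth_incidence(
    params: Mapping[str, GompertzParams],
    bands: Sequence[AgeBand] = default_bands(),
    country_label: str = "synthetic",
) -> IncidenceTable:
    """Gompertz-structured incidence table, rates per 100,000 person-years."""
    entries = {}
    for sex, p in params.items():
        for band, rate in _gompertz_rates(p, bands):
            entries[(sex, band)] = rate
    return IncidenceTable(entries, country_label=country_label)


def synth_mortality(
    params: Mapping[str, GompertzParams],
    bands: Sequence[AgeBand] = default_bands(),
    country_label: str = "synthetic",
) -> MortalityTable:
    """Gompertz-structured mortality table, annual rates per person-year."""
    entries = {}
    for sex, p in params.items():
        for band, rate in _gompertz_rates(p, bands):
            entries[(sex, band)] = rate
    return MortalityTable(entries, country_label=country_label)


def synth_ratio(
    bands: Sequence[AgeBand] = default_bands(),
    ratio_at_50: float = 7.0,
    ratio_at_90: float = 1.3,
    sexes: Sequence[str] = ("M", "F"),
) -> RatioTable:
    """MOF:hip ratio table declining log-linearly between two age anchors.

    The ratio is anchored at ages 50 and 90 and evaluated at band
    midpoints (extrapolated log-linearly beyond the anchors), floored at 1
    since MOF includes hip.  Emulates the observed pattern that non-hip
    major fractures dominate at younger ages while hip fractures catch up
    in the very old.
    """
    if ratio_at_50 < 1 or ratio_at_90 < 1:
        raise ValidationError("ratio anchors must be >= 1")
    slope = (math.log(ratio_at_90) - math.log(ratio_at_50)) / 40.0
    entries = {}
    for sex in sexes:
        for band in bands:
            value = math.exp(math.log(ratio_at_50) + slope * (band.midpoint - 50.0))
            entries[(sex, band)] = max(1.0, value)
    return RatioTable(entries)


def synth_population(
    base_count_at_50: float = 100_000.0,
    decline_per_band: float = 0.18,
    growth_per_year: float = 0.02,
    years: Sequence[int] = (2015, 2020, 2030, 2040, 2050),
    bands: Sequence[AgeBand] = default_bands(),
    seed: int = 0,
    sexes: Sequence[str] = ("M", "F"),
) -> PopulationTable:
    """Synthetic pyramids: geometric decline with age, geometric growth in time.

    count(year, sex, band_i) = base * (1 - decline)^i * (1 + growth)^(year - first)
    times a small seeded lognormal perturbation that is fixed per
    (sex, band) across years, so the total across years still grows
    exactly geometrically at the stated rate.  Emulates a young, growing
    population whose older bands thin out.
    """
    if not isinstance(seed, (int, np.integer)):
        raise ConfigurationError(f"seed must be an integer, got {type(seed).__name__}")
    if not 0 <= decline_per_band < 1:
        raise ValidationError("decline_per_band must be in [0, 1)")
    rng = np.random.default_rng(seed)
    years = sorted(int(y) for y in years)
    first = years[0]
    jitter = {
        (sex, band): float(np.exp(rng.normal(0.0, 0.05)))
        for sex in sexes
        for band in bands
    }
    entries = []
    for year in years:
        growth = (1.0 + growth_per_year) ** (year - first)
        for sex in sexes:
            for i, band in enumerate(bands):
                count = (
                    base_count_at_50
                    * (1.0 - decline_per_band) ** i
                    * growth
                    * jitter[(sex, band)]
                )
                entries.append((year, sex, band.lo, band.hi, count))
    return PopulationTable(entries)


# Default "source country" scenario: moderate-risk hip-fracture epidemiology
# with exponential age rise; fixtures for tests and examples, not estimates
# of any real registry.
DEFAULT_INCIDENCE_PARAMS = {
    "F": GompertzParams(alpha=20.0, beta=0.09, sex="F"),
    "M": GompertzParams(alpha=15.0, beta=0.075, sex="M"),
}
DEFAULT_MORTALITY_PARAMS = {
    "F": GompertzParams(alpha=0.004, beta=0.095, sex="F"),
    "M": GompertzParams(alpha=0.006, beta=0.095, sex="M"),
}
#: Target-country mortality: same age slope, modestly different level, as
#: between two neighbouring countries with similar life expectancy.
DEFAULT_TARGET_MORTALITY_PARAMS = {
    "F": GompertzParams(alpha=0.0044, beta=0.095, sex="F"),
    "M": GompertzParams(alpha=0.0063, beta=0.095, sex="M"),
}


def default_source_model(label: str = "source-authentic") -> FraxModel:
    """The default synthetic source-country model (authentic epidemiology)."""
    return FraxModel(
        hip_incidence=synth_incidence(DEFAULT_INCIDENCE_PARAMS, country_label=label),
        mortality=synth_mortality(DEFAULT_MORTALITY_PARAMS, country_label=label),
        mof_ratio=synth_ratio(),
        rr_model=default_relative_risks(),
        label=label,
    )


def default_target_mortality(label: str = "target") -> MortalityTable:
    """Mortality of the index country that lacks fracture data."""
    return synth_mortality(DEFAULT_TARGET_MORTALITY_PARAMS, country_label=label)


class CohortCounts(NamedTuple):
    fractured: int
    died_first: int
    survived: int


def simulate_cohort(
    model: FraxModel,
    profile: RiskProfile,
    n: int,
    horizon: int = 10,
    seed: int | np.random.Generator = 0,
    outcome: str = "hip",
) -> CohortCounts:
    """Monte-Carlo two-state cohort with the engine's exact yearly hazards.

    Each of ``n`` individuals is followed year by year: the chance of any
    exit in a year is 1 - exp(-(h_f + h_d)) (one exponential draw against
    the total hazard) and an exiting individual fractures with probability
    h_f / (h_f + h_d), otherwise dies first.  Counts always sum to n and
    are reproducible given the seed.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (int, np.integer)) and not isinstance(seed, bool):
        rng = np.random.default_rng(seed)
    else:
        raise ConfigurationError(
            f"seed must be an integer or numpy Generator, got {type(seed).__name__}"
        )
    rr = relative_risk(profile, model.rr_model, outcome)
    fractured = 0
    died = 0
    alive = n
    for t in range(horizon):
        a = profile.age + t
        h_f = model.baseline_hazard(outcome, profile.sex, a) * rr
        h_d = hazard_at(model.mortality, profile.sex, a)
        total = h_f + h_d
        if total == 0.0 or alive == 0:
            continue
        exit_prob = 1.0 - math.exp(-total)
        exits = int(rng.binomial(alive, exit_prob))
        frac_exits = int(rng.binomial(exits, h_f / total)) if exits else 0
        fractured += frac_exits
        died += exits - frac_exits
        alive -= exits
    return CohortCounts(fractured=fractured, died_first=died, survived=alive)
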