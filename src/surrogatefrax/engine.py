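"""Ten-year fracture probability under competing mortality.

The engine follows the standard double-decrement construction: fracture and
death are competing exits from a single "intact" state, with hazards held
constant within each year of age.  For a profile aged ``a`` at entry, year
``t`` (t = 0..9) uses the fracture hazard h_f at age a+t — the baseline
country hazard scaled by the profile's relative-risk multiplier — and the
death hazard h_d at a+t.  With S(0) = 1, the probability of fracturing first
during year t is::

    S(t) * h_f / (h_f + h_d) * (1 - exp(-(h_f + h_d)))

and S(t+1) = S(t) * exp(-(h_f + h_d)).  The 10-year fracture probability is
the sum of the ten yearly contributions.  Relative risks act on fracture
hazards only; mortality is a country-level input.  BMI is recorded but has
no multiplier (probability grids fix it at 26 kg/m²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from surrogatefrax.errors import ConfigurationError, ValidationError
from surrogatefrax.tables import (
    IncidenceTable,
    MortalityTable,
    RatioTable,
    hazard_at,
    require_aligned,
)

#: The six dichotomous clinical risk factors toggled in scenario grids:
#: the standard FRAX set minus secondary osteoporosis (inert once BMD is
#: entered).
CRF_NAMES = (
    "prior_fracture",
    "parent_hip_fracture",
    "smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "alcohol",
)

OUTCOMES = ("hip", "mof")

HORIZON_YEARS = 10


@dataclass(frozen=True)
class RiskProfile:
    """One clinical scenario: age, sex, CRF flags, femoral-neck T-score, BMI.

    ``t_score`` may be ``None`` (BMD not entered).  ``crfs`` is the set of
    risk-factor names that are present; names must come from
    :data:`CRF_NAMES`.
    """

    age: int
    sex: str
    crfs: frozenset[str] = frozenset()
    t_score: float | None = None
    bmi: float = 26.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if not 40 <= self.age <= 90:
            raise ValidationError(f"age {self.age} outside supported range [40, 90]")
        unknown = set(self.crfs) - set(CRF_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown clinical risk factor(s): {sorted(unknown)}")
        object.__setattr__(self, "crfs", frozenset(self.crfs))
        if self.t_score is not None and not -5.0 <= self.t_score <= 2.0:
            raise ValidationError(f"t_score {self.t_score} outside [-5, 2]")
        if not 15.0 <= self.bmi <= 45.0:
            raise ValidationError(f"bmi {self.bmi} outside [15, 45]")

    @property
    def crf_bitmask(self) -> int:
        """Bitmask over :data:`CRF_NAMES` order (bit i = factor i present)."""
        return sum(1 << i for i, name in enumerate(CRF_NAMES) if name in self.crfs)

    @classmethod
    def from_bitmask(
        cls,
        age: int,
        sex: str,
        bitmask: int,
        t_score: float | None = None,
        bmi: float = 26.0,
    ) -> "RiskProfile":
        crfs = frozenset(
            name for i, name in enumerate(CRF_NAMES) if bitmask & (1 << i)
        )
        return cls(age=age, sex=sex, crfs=crfs, t_score=t_score, bmi=bmi)


@dataclass(frozen=True)
class RelativeRiskModel:
    """Multiplicative risk-factor effects on fracture hazards.

    ``rr`` maps (crf_name, outcome) to a relative-risk multiplier; the
    ``gradient_of_risk`` (GR) per outcome is the multiplier per SD decrease
    in femoral-neck T-score, anchored at multiplier 1 for T = 0.
    """

    rr: Mapping[tuple[str, str], float]
    gradient_of_risk: Mapping[str, float]

    def __post_init__(self) -> None:
        rr = dict(self.rr)
        gr = dict(self.gradient_of_risk)
        for (name, outcome), value in rr.items():
            if name not in CRF_NAMES:
                raise ConfigurationError(f"unknown CRF {name!r} in relative-risk table")
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r}")
            if not value > 0:
                raise ConfigurationError(f"relative risk for {name}/{outcome} must be > 0")
        for outcome in OUTCOMES:
            if outcome not in gr:
                raise ConfigurationError(f"gradient_of_risk missing outcome {outcome!r}")
            if not gr[outcome] > 1:
                raise ConfigurationError("gradient_of_risk must be > 1")
        object.__setattr__(self, "rr", rr)
        object.__setattr__(self, "gradient_of_risk", gr)

    def rr_for(self, name: str, outcome: str) -> float:
        try:
            return self.rr[(name, outcome)]
        except KeyError:
            raise ConfigurationError(
                f"no relative risk configured for CRF {name!r}, outcome {outcome!r}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RelativeRiskModel":
        """Load from YAML: ``relative_risks: [{crf, outcome, rr}, ...]`` plus
        ``gradient_of_risk: {hip: .., mof: ..}``."""
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        try:
            rows = doc["relative_risks"]
            gr = doc["gradient_of_risk"]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"{path}: malformed relative-risk config") from exc
        rr = {(row["crf"], row["outcome"]): float(row["rr"]) for row in rows}
        return cls(rr=rr, gradient_of_risk={k: float(v) for k, v in gr.items()})


def default_relative_risks() -> RelativeRiskModel:
    """A plausible FRAX-like relative-risk configuration.

    The authentic calibration is proprietary and unpublished; these defaults
    sit in the ranges reported by the underlying meta-analyses and serve as
    the package's reference configuration, not as estimates of FRAX itself.
    Each factor's multiplier (and the gradient of risk) is applied
    identically to both outcomes, which preserves the superset relation
    P(hip) <= P(MOF) under the multiplicative hazard composition for any
    MOF:hip ratio >= 1; outcome-specific values remain supported
    configuration.
    """
    per_crf = {
        "prior_fracture": 1.85,
        "parent_hip_fracture": 1.9,
        "smoking": 1.25,
        "glucocorticoids": 1.6,
        "rheumatoid_arthritis": 1.45,
        "alcohol": 1.4,
    }
    rr = {}
    for name, value in per_crf.items():
        rr[(name, "hip")] = value
        rr[(name, "mof")] = value
    return RelativeRiskModel(rr=rr, gradient_of_risk={"hip": 1.6, "mof": 1.6})


@dataclass(frozen=True)
class FraxModel:
    """One country model: hip incidence + mortality + MOF ratios + relative risks."""

    hip_incidence: IncidenceTable
    mortality: MortalityTable
    mof_ratio: RatioTable
    rr_model: RelativeRiskModel
    label: str = ""

    def __post_init__(self) -> None:
        missing = set(self.hip_incidence.sexes) - set(self.mortality.sexes)
        if missing:
            raise ValidationError(f"mortality table lacks sexes {sorted(missing)}")
        missing = set(self.hip_incidence.sexes) - set(self.mof_ratio.sexes)
        if missing:
            raise ValidationError(f"ratio table lacks sexes {sorted(missing)}")

    def baseline_hazard(self, outcome: str, sex: str, age: int) -> float:
        """Baseline (no risk factors) fracture hazard per person-year."""
        h = hazard_at(self.hip_incidence, sex, age)
        if outcome == "hip":
            return h
        if outcome == "mof":
            return h * self.mof_ratio.value_at(sex, age)
        raise ConfigurationError(f"unknown outcome {outcome!r}")


def relative_risk(profile: RiskProfile, rr_model: RelativeRiskModel, outcome: str) -> float:
    """Profile's multiplicative risk relative to a no-CRF, T = 0 individual.

    The product of the per-CRF relative risks for the set flags, times
    GR^(-t_score) when a T-score is entered (so a T-score of -1 multiplies by
    GR, and +1 divides by it).  Returns exactly 1 for an empty profile.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    multiplier = 1.0
    for name in sorted(profile.crfs):
        multiplier *= rr_model.rr_for(name, outcome)
    if profile.t_score is not None:
        multiplier *= rr_model.gradient_of_risk[outcome] ** (-profile.t_score)
    return multiplier


def mof_incidence(hip: IncidenceTable, ratio: RatioTable) -> IncidenceTable:
    """Impute MOF incidence from hip incidence via MOF:hip ratios.

    Requires identical band edges per sex; the output carries the same bands
    with each band's rate multiplied by its ratio.
    """
    require_aligned(hip, ratio, "mof_incidence")
    entries = {
        key: rate * ratio.entries[key] for key, rate in hip.entries.items()
    }
    return IncidenceTable(entries, country_label=hip.country_label)


def _yearly_hazards(
    profile: RiskProfile, model: FraxModel, outcome: str
) -> tuple[list[float], list[float]]:
    rr = relative_risk(profile, model.rr_model, outcome)
    h_f = []
    h_d = []
    for t in range(HORIZON_YEARS):
        a = profile.age + t
        h_f.append(model.baseline_hazard(outcome, profile.sex, a) * rr)
        h_d.append(hazard_at(model.mortality, profile.sex, a))
    return h_f, h_d


def ten_year_decomposition(
    profile: RiskProfile, model: FraxModel, outcome: str
) -> tuple[float, float, float]:
    """(P(fracture first), P(death first), P(survive 10 y event-free)).

    The three terms sum to 1: fracture is absorbing and death is computed
    symmetrically with cause-split h_d/(h_f + h_d).
    """
    h_f, h_d = _yearly_hazards(profile, model, outcome)
    s = 1.0
    p_frac = 0.0
    p_death = 0.0
    for hf, hd in zip(h_f, h_d):
        total = hf + hd
        if total == 0.0:
            continue
        exit_prob = s * (1.0 - math.exp(-total))
        p_frac += exit_prob * hf / total
        p_death += exit_prob * hd / total
        s *= math.exp(-total)
    return p_frac, p_death, s


def ten_year_probability(profile: RiskProfile, model: FraxModel, outcome: str) -> float:
    """10-year probability of the outcome fracture under competing mortality."""
    return ten_year_decomposition(profile, model, outcome)[0]
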