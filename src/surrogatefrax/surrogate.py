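"""Surrogate model construction and clinical-scenario grid evaluation.

A surrogate country model keeps the source country's fracture epidemiology
(hip incidence, MOF:hip ratios, relative risks) and swaps in the index
country's mortality — the recommended construction when a country has
reliable death registration but no usable fracture registry.

The comparison protocol evaluates both models over the full factorial grid
of clinical scenarios: every combination of the six dichotomous risk
factors (2^6 = 64) crossed with femoral-neck T-scores from 0 to -3.5 SD in
0.5 SD steps (8 values) at fixed BMI 26 kg/m², i.e. 512 profiles per
(age, sex), at ages 50, 60, 70 and 80 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from surrogatefrax.engine import (
    CRF_NAMES,
    FraxModel,
    RiskProfile,
    ten_year_probability,
)
from surrogatefrax.errors import SurrogateFraxError, ValidationError
from surrogatefrax.tables import MortalityTable

GRID_COLUMNS = [
    "profile_id",
    "age",
    "sex",
    "crf_bitmask",
    "t_score",
    "model",
    "outcome",
    "probability",
]

DEFAULT_AGES = (50, 60, 70, 80)
DEFAULT_SEXES = ("M", "F")
DEFAULT_T_SCORES = tuple(-0.5 * i for i in range(8))  # 0.0 .. -3.5
DEFAULT_BMI = 26.0


def profile_id(profile: RiskProfile) -> str:
    """Stable deterministic id: age, sex, zero-padded CRF bitmask, T-score.

    Lexicographic order of ids within one (age, sex) equals (bitmask,
    descending T-score) order, so paired comparisons across models align
    without joins on floating-point values.
    """
    t = "none" if profile.t_score is None else f"{-profile.t_score:04.1f}"
    return f"a{profile.age:02d}_{profile.sex}_c{profile.crf_bitmask:02d}_t{t}"


@dataclass(frozen=True)
class ScenarioGrid:
    """Expanded factorial grid of risk profiles."""

    ages: tuple[int, ...]
    sexes: tuple[str, ...]
    t_scores: tuple[float, ...]
    profiles: tuple[RiskProfile, ...]

    def __len__(self) -> int:
        return len(self.profiles)


def make_grid(
    ages=DEFAULT_AGES,
    sexes=DEFAULT_SEXES,
    t_scores=DEFAULT_T_SCORES,
    bmi: float = DEFAULT_BMI,
    crf_names=CRF_NAMES,
) -> ScenarioGrid:
    """Build the factorial scenario grid.

    With the defaults each (age, sex) stratum expands to 2^6 x 8 = 512
    profiles.  ``crf_names`` may be restricted (for small exact tests); the
    profile count is |ages| x |sexes| x 2^|crf_names| x |t_scores|.
    """
    ages = tuple(int(a) for a in ages)
    sexes = tuple(sexes)
    t_scores = tuple(float(t) for t in t_scores)
    if not ages or not sexes or not t_scores:
        raise ValidationError("grid needs at least one age, sex and T-score")
    unknown = set(crf_names) - set(CRF_NAMES)
    if unknown:
        raise ValidationError(f"unknown CRF names {sorted(unknown)}")
    bit_of = {name: 1 << CRF_NAMES.index(name) for name in crf_names}
    profiles = []
    for age in ages:
        for sex in sexes:
            for subset in range(1 << len(crf_names)):
                mask = 0
                for i, name in enumerate(crf_names):
                    if subset & (1 << i):
                        mask |= bit_of[name]
                for t in t_scores:
                    profiles.append(
                        RiskProfile.from_bitmask(age, sex, mask, t_score=t, bmi=bmi)
                    )
    profiles.sort(key=lambda p: (p.age, p.sex, p.crf_bitmask, -p.t_score))
    return ScenarioGrid(ages=ages, sexes=sexes, t_scores=t_scores, profiles=tuple(profiles))


def build_surrogate(
    source: FraxModel, target_mortality: MortalityTable, label: str
) -> FraxModel:
    """Pair the source model's fracture epidemiology with target mortality.

    The returned model shares (value-identical) hip incidence, MOF ratios
    and relative risks with the source; only the mortality table and label
    change.  The target mortality must cover every sex and age span the
    source incidence covers.
    """
    for sex in source.hip_incidence.sexes:
        if sex not in target_mortality.sexes:
            raise ValidationError(f"target mortality lacks sex {sex}")
        src_lo, src_hi = source.hip_incidence.age_span(sex)
        tgt_lo, tgt_hi = target_mortality.age_span(sex)
        if tgt_lo > src_lo or tgt_hi < src_hi:
            raise ValidationError(
                f"target mortality covers [{tgt_lo}, {tgt_hi}) for sex {sex}, "
                f"needs [{src_lo}, {src_hi})"
            )
    return replace(source, mortality=target_mortality, label=label)


def evaluate_grid(model: FraxModel, grid: ScenarioGrid) -> pd.DataFrame:
    """Hip and MOF 10-year probabilities for every grid profile.

    Returns a tidy frame with one row per (profile, outcome) — two rows per
    profile — in the columns :data:`GRID_COLUMNS`.  Deterministic given
    inputs.
    """
    rows = []
    for profile in grid.profiles:
        pid = profile_id(profile)
        for outcome in ("hip", "mof"):
            try:
                p = ten_year_probability(profile, model, outcome)
            except SurrogateFraxError as exc:
                raise type(exc)(f"profile {pid}: {exc}") from exc
            rows.append(
                (pid, profile.age, profile.sex, profile.crf_bitmask,
                 profile.t_score, model.label, outcome, p)
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
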