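import math

import pytest
from hypothesis import given, settings, strategies as st

from surrogatefrax.engine import (
    CRF_NAMES,
    FraxModel,
    RelativeRiskModel,
    RiskProfile,
    default_relative_risks,
    mof_incidence,
    relative_risk,
    ten_year_decomposition,
    ten_year_probability,
)
from surrogatefrax.errors import AlignmentError, ConfigurationError, ValidationError
from surrogatefrax.tables import IncidenceTable, MortalityTable, RatioTable

from conftest import constant_model


def rr_model(value: float = 2.0, gr: float = 1.5) -> RelativeRiskModel:
    rr = {(name, outcome): value for name in CRF_NAMES for outcome in ("hip", "mof")}
    return RelativeRiskModel(rr=rr, gradient_of_risk={"hip": gr, "mof": gr})


class TestRelativeRisk:
    def test_empty_profile_is_unity(self):
        p = RiskProfile(age=60, sex="F", t_score=0.0)
        assert relative_risk(p, rr_model(), "hip") == 1.0
        assert relative_risk(RiskProfile(age=60, sex="F"), rr_model(), "mof") == 1.0

    def test_one_crf_with_bmd(self):
        p = RiskProfile(age=60, sex="F", crfs=frozenset({"smoking"}), t_score=-1.0)
        assert relative_risk(p, rr_model(2.0, 1.5), "hip") == pytest.approx(3.0)

    def test_inert_crfs_leave_only_bmd_gradient(self):
        p = RiskProfile(age=60, sex="F", crfs=frozenset(CRF_NAMES), t_score=-3.5)
        assert relative_risk(p, rr_model(1.0, 1.6), "hip") == pytest.approx(1.6**3.5)

    def test_unknown_crf_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            RiskProfile(age=60, sex="F", crfs=frozenset({"levitation"}))

    def test_t_score_above_zero_gives_credit(self):
        p = RiskProfile(age=60, sex="F", t_score=1.0)
        assert relative_risk(p, rr_model(2.0, 1.5), "hip") == pytest.approx(1 / 1.5)


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": 39}, {"age": 91}, {"sex": "X"},
            {"t_score": -5.5}, {"t_score": 2.5}, {"bmi": 10.0}, {"bmi": 50.0},
        ],
    )
    def test_out_of_range_fields_rejected(self, kwargs):
        base = {"age": 60, "sex": "F"}
        base.update(kwargs)
        with pytest.raises((ValidationError, ConfigurationError)):
            RiskProfile(**base)


class TestMofIncidence:
    def test_rates_scaled_by_ratio(self):
        hip = IncidenceTable([("F", 50, None, 100.0)])
        ratio = RatioTable([("F", 50, None, 4.0)])
        assert mof_incidence(hip, ratio).entries[("F", next(iter(hip.bands("F"))))] == 400.0

    def test_unit_ratio_is_identity(self):
        hip = IncidenceTable([("F", 50, 70, 100.0), ("F", 70, None, 300.0)])
        ratio = RatioTable([("F", 50, 70, 1.0), ("F", 70, None, 1.0)])
        assert mof_incidence(hip, ratio).entries == hip.entries

    def test_band_mismatch_is_alignment_error(self):
        hip = IncidenceTable([("F", 50, 55, 100.0), ("F", 55, None, 300.0)])
        ratio = RatioTable([("F", 50, None, 2.0)])
        with pytest.raises(AlignmentError):
            mof_incidence(hip, ratio)


class TestTenYearProbability:
    """Closed-form checks of the double-decrement construction."""

    def test_zero_fracture_hazard_gives_zero(self):
        model = constant_model(0.0, 0.05)
        p = RiskProfile(age=60, sex="F")
        assert ten_year_probability(p, model, "hip") == 0.0
        assert ten_year_probability(p, model, "mof") == 0.0

    def test_single_decrement_closed_form(self):
        # h_f = 0.01 constant, no mortality: P = 1 - exp(-0.1)
        model = constant_model(1000.0, 0.0)
        p = RiskProfile(age=60, sex="F")
        assert ten_year_probability(p, model, "hip") == pytest.approx(
            1 - math.exp(-0.1), abs=1e-12
        )

    def test_competing_risk_closed_form(self):
        # h_f = 0.01, h_d = 0.02 constant: P = (1/3)(1 - exp(-0.3))
        model = constant_model(1000.0, 0.02)
        p = RiskProfile(age=60, sex="M")
        assert ten_year_probability(p, model, "hip") == pytest.approx(
            (1 / 3) * (1 - math.exp(-0.3)), abs=1e-12
        )

    def test_zero_total_hazard_year_contributes_nothing(self):
        model = constant_model(0.0, 0.0)
        p = RiskProfile(age=60, sex="F")
        assert ten_year_decomposition(p, model, "hip") == (0.0, 0.0, 1.0)

    def test_conservation_of_probability(self, source_model):
        """Fracture + death-first + event-free survival account for everyone."""
        for age in (50, 65, 80):
            for sex in ("M", "F"):
                p = RiskProfile(
                    age=age, sex=sex,
                    crfs=frozenset({"prior_fracture", "smoking"}), t_score=-2.0,
                )
                frac, death, surv = ten_year_decomposition(p, source_model, "mof")
                assert frac + death + surv == pytest.approx(1.0, abs=1e-12)
                assert 0.0 <= frac <= 1.0

    def test_additional_crf_strictly_increases_risk(self, source_model):
        base = RiskProfile(age=70, sex="F", crfs=frozenset({"smoking"}), t_score=-1.5)
        for extra in set(CRF_NAMES) - {"smoking"}:
            worse = RiskProfile(
                age=70, sex="F", crfs=base.crfs | {extra}, t_score=-1.5
            )
            for outcome in ("hip", "mof"):
                assert ten_year_probability(worse, source_model, outcome) > ten_year_probability(
                    base, source_model, outcome
                )

    def test_lower_t_score_strictly_increases_risk(self, source_model):
        probs = [
            ten_year_probability(
                RiskProfile(age=70, sex="M", t_score=t), source_model, "hip"
            )
            for t in (0.0, -0.5, -1.0, -1.5, -2.0)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_higher_mortality_never_increases_fracture_probability(self):
        p = RiskProfile(age=60, sex="F", t_score=-2.0)
        probs = [
            ten_year_probability(p, constant_model(500.0, h_d), "hip")
            for h_d in (0.0, 0.01, 0.05, 0.2)
        ]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_hip_never_exceeds_mof_under_default_config(self, source_model):
        for age in (50, 70, 80):
            for t in (0.0, -3.5):
                for mask in (0, 63):
                    p = RiskProfile.from_bitmask(age, "F", mask, t_score=t)
                    assert ten_year_probability(p, source_model, "hip") <= ten_year_probability(
                        p, source_model, "mof"
                    )

    def test_coverage_gap_raises_with_no_extrapolation(self):
        short = MortalityTable([("F", 50, 90, 0.01)])
        model = FraxModel(
            hip_incidence=IncidenceTable([("F", 50, None, 100.0)]),
            mortality=short,
            mof_ratio=RatioTable([("F", 50, None, 2.0)]),
            rr_model=default_relative_risks(),
        )
        p = RiskProfile(age=85, sex="F")  # needs mortality through age 94
        with pytest.raises(Exception, match="outside coverage"):
            ten_year_probability(p, model, "hip")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        rate=st.floats(0.0, 5000.0),
        mort=st.floats(0.0, 0.5),
        ratio=st.floats(1.0, 8.0),
        mask=st.integers(0, 63),
        t=st.floats(-3.5, 0.0),
        age=st.integers(50, 80),
        sex=st.sampled_from(["M", "F"]),
    )
    def test_probability_bounds_property(self, rate, mort, ratio, mask, t, age, sex):
        """Probabilities stay in [0, 1] and hip <= MOF across random models."""
        model = constant_model(rate, mort, ratio)
        p = RiskProfile.from_bitmask(age, sex, mask, t_score=t)
        hip = ten_year_probability(p, model, "hip")
        mof = ten_year_probability(p, model, "mof")
        assert 0.0 <= hip <= 1.0
        assert hip <= mof + 1e-15


class TestRelativeRiskModelConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rr.yaml"
        path.write_text(
            "relative_risks:\n"
            "  - {crf: smoking, outcome: hip, rr: 1.3}\n"
            "  - {crf: smoking, outcome: mof, rr: 1.2}\n"
            "gradient_of_risk: {hip: 2.0, mof: 1.5}\n"
        )
        model = RelativeRiskModel.from_yaml(path)
        assert model.rr_for("smoking", "hip") == 1.3
        assert model.gradient_of_risk["mof"] == 1.5

    def test_gradient_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            RelativeRiskModel(rr={}, gradient_of_risk={"hip": 1.0, "mof": 1.5})

    def test_missing_rr_lookup_is_configuration_error(self):
        model = RelativeRiskModel(rr={}, gradient_of_risk={"hip": 1.5, "mof": 1.5})
        p = RiskProfile(age=60, sex="F", crfs=frozenset({"smoking"}))
        with pytest.raises(ConfigurationError):
            relative_risk(p, model, "hip")
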