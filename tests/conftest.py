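import pytest

from surrogatefrax import synthetic
from surrogatefrax.engine import FraxModel, RelativeRiskModel, default_relative_risks
from surrogatefrax.tables import IncidenceTable, MortalityTable, RatioTable


def constant_model(
    hip_rate_per_100k: float,
    mortality_rate: float,
    ratio: float = 1.0,
    rr_model: RelativeRiskModel | None = None,
) -> FraxModel:
    """Model with age/sex-constant hazards on one open-ended band (both sexes)."""
    entries = lambda v: [("F", 50, None, v), ("M", 50, None, v)]
    return FraxModel(
        hip_incidence=IncidenceTable(entries(hip_rate_per_100k)),
        mortality=MortalityTable(entries(mortality_rate)),
        mof_ratio=RatioTable(entries(ratio)),
        rr_model=rr_model or default_relative_risks(),
        label="constant",
    )


@pytest.fixture(scope="session")
def source_model() -> FraxModel:
    return synthetic.default_source_model()


@pytest.fixture(scope="session")
def target_mortality():
    return synthetic.default_target_mortality()
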