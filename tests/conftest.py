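import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import endocost as ec


@pytest.fixture(scope="session")
def rates() -> ec.CostRates:
    return ec.CostRates(theatre_rate=14.65, stay_rate=681.0)


@pytest.fixture(scope="session")
def lps_spec() -> ec.EquipmentSpec:
    return ec.EquipmentSpec("laparoscopic tower", 140_000.0, 1000)


@pytest.fixture(scope="session")
def rbt_spec() -> ec.EquipmentSpec:
    return ec.EquipmentSpec("robotic platform", 2_000_000.0, 1000)


@pytest.fixture(scope="session")
def ref_summaries() -> dict[ec.Arm, ec.ArmCostSummary]:
    return ec.reference_summaries()


@pytest.fixture(scope="session")
def ref_ratios() -> dict[ec.Arm, ec.StayRatio]:
    return ec.reference_ratios()


@pytest.fixture(scope="session")
def small_cohort() -> list[ec.PatientRecord]:
    """Fixed small synthetic cohort (both arms, study-arm defaults)."""
    return ec.generate_cohort(ec.default_config(seed=7))
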