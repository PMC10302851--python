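import pytest
from hypothesis import HealthCheck, settings

from vancotdm import pk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def q12_regimen() -> pk.DosingRegimen:
    """1 g infused over 1 h every 12 h."""
    return pk.DosingRegimen(dose=1000.0, tau=12.0, t_in=1.0)


@pytest.fixture
def adult_male() -> pk.PatientDemographics:
    return pk.PatientDemographics(
        sex="male", age=40, weight=72.0, height=1.75, baseline_scr=1.0
    )
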