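import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lungct import default_phantom
from lungct.io import RawMeasurement, ScanProtocol


@pytest.fixture(scope="session")
def phantom():
    return default_phantom("foam1_basis")


@pytest.fixture(scope="session")
def water_phantom():
    return default_phantom("water_basis")


@pytest.fixture
def nominal_measurement(phantom):
    """Perfectly calibrated scan: measured values equal the nominals."""
    return RawMeasurement(
        protocol=ScanProtocol(scanner_id="nominal", kvp=120.0, ctdi=3.0),
        values={m.name: m.nominal_ct for m in phantom.materials},
    )


def random_measurement(rng, phantom, spread=15.0):
    """Nominal values perturbed by uniform offsets (physically plausible)."""
    values = {
        m.name: m.nominal_ct + rng.uniform(-spread, spread)
        for m in phantom.materials
    }
    values["Air"] = max(values["Air"], -1090.0)
    return RawMeasurement(
        protocol=ScanProtocol(scanner_id="rand", kvp=120.0, ctdi=3.0),
        values=values,
    )
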