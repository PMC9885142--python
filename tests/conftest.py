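import pytest

from navcea.calibration import default_calibration


@pytest.fixture(scope="session")
def calibration():
    """Calibration against the published anchors (cached for the session)."""
    return default_calibration()


@pytest.fixture(scope="session")
def calibrated_params(calibration):
    return calibration.apply()


@pytest.fixture(scope="session")
def conventions(calibration):
    return calibration.conventions
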