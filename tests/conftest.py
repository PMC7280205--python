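import logging

import pytest

from plethysniff.metrics import WindowSpec
from plethysniff.simulate import (
    BreathingModelParams,
    DetectionModelParams,
    OdorKineticsParams,
    SessionDesign,
)

logging.getLogger("plethysniff").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    """Desk-scale session design (same trial structure as the default)."""
    return SessionDesign.scaled()


@pytest.fixture(scope="session")
def breathing():
    return BreathingModelParams()


@pytest.fixture(scope="session")
def kinetics():
    return OdorKineticsParams()


@pytest.fixture(scope="session")
def detection():
    return DetectionModelParams()


@pytest.fixture(scope="session")
def window():
    return WindowSpec()


@pytest.fixture(scope="session")
def quiet_breathing():
    """Deterministic, noiseless breathing (zero cycle jitter)."""
    return BreathingModelParams(
        eupnea_sd_hz=0.0,
        sniff_sd_hz=0.0,
        noise_sd_au=0.0,
        spont_bout_rate_per_min=0.0,
        reaction_sd_s=0.0,
    )


@pytest.fixture(scope="session")
def clean_design():
    """Desk-scale design without artifacts or common-mode noise."""
    return SessionDesign.scaled(artifact_amplitude_au=0.0, common_noise_sd_au=0.0)
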