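import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("package")

import pepbiophys as pb

WT_SEQUENCE = "GWAEGLHARPASIFVRAATATG"


@pytest.fixture
def wild_type():
    return pb.parse_peptide("wild-type", WT_SEQUENCE)


@pytest.fixture
def tfe_truth():
    """Two-state ground truth in the wild-type parameter regime."""
    return pb.HelixCoilFit(
        m=166.0, tfe_half=23.2,
        theta_D0=-1000.0, slope_D=-20.0, theta_H0=-16000.0, slope_H=-60.0,
    )


@pytest.fixture
def itc_design():
    """19 x 2 µL injections, 200 µM syringe into 20 µM cell at 25 °C."""
    return pb.default_itc_experiment()
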