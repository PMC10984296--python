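import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from neopk import DosingEvent, PopulationPrior, StructuralParameters

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture
def neonatal_params() -> StructuralParameters:
    """Structural parameters in the reported neonatal range."""
    return StructuralParameters(cl=0.22, v=2.18, ka=1.0)


@pytest.fixture
def iv_event() -> DosingEvent:
    """0.5 mg/kg for a 2.8 kg neonate as a 15-min infusion at t=0."""
    return DosingEvent(start_time=0.0, amount=1.4, route="iv_infusion",
                       duration=0.25)


@pytest.fixture
def prior() -> PopulationPrior:
    return PopulationPrior(tv_cl=2.4, tv_v=58.0, tv_ka=1.0, ref_weight=70.0,
                           omega=np.diag([0.1, 0.1]), sigma_prop=0.1)
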