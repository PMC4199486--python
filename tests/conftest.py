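import numpy as np
import pytest

from cadwave import SimConfig1D, TemporalGradient, condition_preset, simulate_1d
from cadwave.gradient import GradientDescriptors


@pytest.fixture(scope="session")
def wt_gradient() -> TemporalGradient:
    return condition_preset("WT")


@pytest.fixture(scope="session")
def wt_pattern(wt_gradient):
    """Full wild-type blastoderm run, 13.5-23 h AEL; shared across tests."""
    return simulate_1d(SimConfig1D(), wt_gradient)


@pytest.fixture(scope="session")
def static_wt() -> TemporalGradient:
    """WT steady shape with no buildup and no retraction."""
    return TemporalGradient(
        steady=GradientDescriptors(1.0, 0.40, 2.5),
        t_on=13.5, tau=0.0, retraction_onset=np.inf, retraction_speed=0.0,
    )
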