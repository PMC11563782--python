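import numpy as np
import pytest

from hyphabend.channel_flow import ChannelGeometry, Fluid, FlowCondition
from hyphabend.beam_mechanics import HyphaGeometry


@pytest.fixture
def water() -> Fluid:
    return Fluid()


@pytest.fixture
def center_geom() -> ChannelGeometry:
    """Center-configuration measurement chamber (defaults of the study)."""
    return ChannelGeometry(width=500.0, height=90.0, configuration="center")


@pytest.fixture
def floor_geom() -> ChannelGeometry:
    """Floor-configuration chamber: same molded footprint, half the height."""
    return ChannelGeometry(width=500.0, height=45.0, configuration="floor")


@pytest.fixture
def flow() -> FlowCondition:
    return FlowCondition.from_ul_min(1.0)


@pytest.fixture
def hypha() -> HyphaGeometry:
    return HyphaGeometry(radius=1.4, wall_thickness=0.287, length=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
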