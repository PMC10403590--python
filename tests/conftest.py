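import numpy as np
import pytest

from obskit.core import LayeredMedium, SensorArray
from obskit.forward import Phantom, PulseModel, simulate_channels


@pytest.fixture
def small_array() -> SensorArray:
    """16×16, 0.5 mm pitch aperture — small enough for fast round trips."""
    return SensorArray.regular_grid(
        nx=16, ny=16, element_width=0.4, gap=0.1,
        center_frequency=7.8, fractional_bandwidth=1.0, sampling_rate=50.0,
    )


@pytest.fixture
def homogeneous_medium() -> LayeredMedium:
    return LayeredMedium([(np.inf, 1500.0)])


@pytest.fixture
def two_layer_medium() -> LayeredMedium:
    return LayeredMedium([(2.0, 1650.0), (np.inf, 1480.0)])


@pytest.fixture
def pulse() -> PulseModel:
    return PulseModel(center_frequency=7.8, fractional_bandwidth=1.0)


@pytest.fixture
def point_channels(small_array, homogeneous_medium, pulse):
    """Channels for a single point source at (1.0, −0.5, 4.0) mm."""
    phantom = Phantom(point_sources=[((1.0, -0.5, 4.0), 1.0)])
    data = simulate_channels(phantom, small_array, homogeneous_medium, pulse)
    return data, (1.0, -0.5, 4.0)
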