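import numpy as np
import pytest

from iscatsim.imaging import OpticalTrain
from iscatsim.layers import LayerStack, PlaneWaveSpec, incident_field
from iscatsim.materials import air, glass, gold, polystyrene, water


@pytest.fixture(scope="session")
def water_glass():
    return LayerStack.two_media(water(), glass())


@pytest.fixture(scope="session")
def air_glass():
    return LayerStack.two_media(air(), glass())


@pytest.fixture(scope="session")
def matched_water():
    return LayerStack.two_media(water(), water())


@pytest.fixture(scope="session")
def tm_drive_20(water_glass):
    """Canonical drive: TM plane wave at -20 deg impinging from below."""
    wave = PlaneWaveSpec(
        wavelength_nm=520.0, polar_angle_deg=-20.0, polarization="TM", direction="up"
    )
    return incident_field(water_glass, wave)


@pytest.fixture(scope="session")
def oil_train():
    """High-NA oil-immersion detection train (NA 1.3, n = 1.5)."""
    return OpticalTrain.from_magnification(
        NA=1.3, n=1.5, n_prime=1.0, magnification=133.33
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
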