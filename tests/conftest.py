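import math

import numpy as np
import pytest

import glucocest as gc


@pytest.fixture(scope="session")
def invitro_acq():
    """In-vitro acquisition: 0.1 ppm over +/-10 ppm, 7 T, small matrix."""
    return gc.AcquisitionConfig(
        B0=7.0, offsets=tuple(gc.make_offset_list(0.1, 10.0)), matrix=(48, 48)
    )


@pytest.fixture(scope="session")
def invivo_acq():
    """In-vivo acquisition: 0.2 ppm over +/-6 ppm, 7 T."""
    return gc.AcquisitionConfig(
        B0=7.0, offsets=tuple(gc.make_offset_list(0.2, 6.0)), matrix=(32, 32)
    )


@pytest.fixture(scope="session")
def sat3():
    return gc.SaturationScheme(3.0, 5.0)


@pytest.fixture(scope="session")
def sat2():
    return gc.SaturationScheme(2.0, 5.0)


@pytest.fixture(scope="session")
def water7():
    return gc.water_preset(7.0, "solution")


@pytest.fixture(scope="session")
def noisefree_phantom(invitro_acq, sat3):
    """Seven-vial glucose phantom at the study pH list, noise-free."""
    return gc.generate_phantom(
        gc.glucose(), acq=invitro_acq, sat=sat3, snr=math.inf, seed=0
    )


@pytest.fixture(scope="session")
def noisefree_phantom_map(noisefree_phantom):
    return gc.st_map(noisefree_phantom.stack)


@pytest.fixture(scope="session")
def glucose_spectrum(invitro_acq, sat3, water7):
    """Noise-free 20 mM glucose spectrum at pH 6.2."""
    return gc.simulate_zspectrum(gc.glucose(), 20.0, 6.2, water7, sat3, invitro_acq)
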