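import numpy as np
import pytest

import saxstrain as sx


@pytest.fixture(scope="session")
def mini_geometry() -> sx.Geometry:
    """Small detector resolving the collagen ring fast (tests only)."""
    return sx.Geometry(
        beam_center_xy=(128.0, 127.0),
        distance_mm=1500.0,
        wavelength_a=sx.energy_to_wavelength(10.0),
        pixel_size_um=100.0,
        detector_shape=(256, 256),
    )


@pytest.fixture(scope="session")
def mini_waxd_geometry() -> sx.Geometry:
    """Small detector resolving the mineral (002) ring."""
    return sx.Geometry(
        beam_center_xy=(128.0, 127.0),
        distance_mm=30.0,
        wavelength_a=sx.energy_to_wavelength(10.0),
        pixel_size_um=100.0,
        detector_shape=(256, 256),
    )


@pytest.fixture(scope="session")
def mini_calibrant(mini_geometry) -> sx.DetectorFrame:
    return sx.simulate_calibrant_frame(mini_geometry, ring_d=[200.0], seed=11)


def flat_azimuthal_profile(value: float = 1.0, n: int = 720) -> sx.AzimuthalProfile:
    width = 360.0 / n
    chi = -180.0 + (np.arange(n) + 0.5) * width
    return sx.AzimuthalProfile(
        chi=chi,
        intensity=np.full(n, value),
        n_pixels=np.full(n, 10),
        q_band=(0.009, 0.010),
    )
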