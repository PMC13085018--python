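"""Shared fixtures: reduced-size optical configurations for fast tests.

The default production grid (129-point pupil, 150² pixels) is only used
in the end-to-end anchor tests; property and unit tests run on smaller
grids where the physics (parity, conservation, scaling laws) is
identical.
"""

import pytest

from polarsliver import OpticalConfig


@pytest.fixture(scope="session")
def small_config() -> OpticalConfig:
    """Reduced grid, full default optics (NA 1.45, index mismatch)."""
    return OpticalConfig(pupil_grid_n=41, image_size=40)


@pytest.fixture(scope="session")
def small_config_low_na() -> OpticalConfig:
    return OpticalConfig(pupil_grid_n=41, image_size=40, numerical_aperture=0.1)


@pytest.fixture(scope="session")
def matched_config() -> OpticalConfig:
    """Index-matched stack: unit Fresnel transmission, no SAF ring."""
    return OpticalConfig(
        pupil_grid_n=41, image_size=40,
        n_medium=1.516, n_coverslip=1.516, n_immersion=1.516,
    )


@pytest.fixture(scope="session")
def toy_config() -> OpticalConfig:
    """8×8-pixel toy model for Monte-Carlo Fisher cross-checks."""
    return OpticalConfig(
        pupil_grid_n=21, image_size=8, pixel_size=680.0 / (2 * 1.45),
        subpixel_oversampling=2,
    )


@pytest.fixture(scope="session")
def default_config() -> OpticalConfig:
    """The production configuration used for all headline numbers."""
    return OpticalConfig()
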