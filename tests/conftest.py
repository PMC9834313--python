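import numpy as np
import pytest

from irispec import (
    LorentzianBand,
    SphereGeometry,
    VoxelDispersion,
    WavenumberGrid,
)


@pytest.fixture
def single_band_model() -> VoxelDispersion:
    """The worked single-band example: center 1000 cm^-1, height 0.1, width 50."""
    return VoxelDispersion(
        bands=(LorentzianBand(center=1000.0, height=0.1, width=50.0),),
        n_infinity=1.5,
    )


@pytest.fixture
def midir_grid() -> WavenumberGrid:
    """A coarse mid-IR grid, cheap enough for forward-model tests."""
    return WavenumberGrid.regular(500.0, 4000.0, 20.0)


@pytest.fixture
def sphere_10um() -> SphereGeometry:
    return SphereGeometry(outer_radius=10.0)


@pytest.fixture
def layered_10_8() -> SphereGeometry:
    return SphereGeometry(outer_radius=10.0, core_radius=8.0)
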