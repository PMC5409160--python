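"""Shared fixtures: small grids and fields sized for fast unit tests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from shearwave import (
    DisplacementField,
    ExcitationSpec,
    GridSpec,
    simulate_displacements,
)
from shearwave import presets


@pytest.fixture(scope="session")
def tiny_grid():
    """Small 4-D grid (fast FFTs, odd/even axis mix)."""
    return GridSpec(((0.0, 6.3), (-1.5, 1.5), (18.0, 24.0)), (0.1, 0.1, 0.1), 10.0, 6.0)


@pytest.fixture(scope="session")
def plane_pulse_field(tiny_grid):
    """Zero-mean wavelet traveling toward +x at 1 m/s, uniform in y and z."""
    x = tiny_grid.x
    t = tiny_grid.times
    s = x[:, None] - 1.0 * t[None, :] - 2.0
    # Morlet-style: zero-mean (little energy on the DC lines), unique peak
    w = np.cos(2 * np.pi * 0.7 * s) * np.exp(-(s**2) / (2 * 0.55**2))
    data = np.broadcast_to(w[:, None, None, :], tiny_grid.shape).copy()
    return DisplacementField(data, tiny_grid)


@pytest.fixture(scope="session")
def homog_field():
    """Homogeneous 3 kPa phantom simulated on a reduced grid."""
    grid = GridSpec(((0.0, 8.0), (-1.2, 1.2), (18.0, 24.0)), (0.2, 0.2, 0.2), 10.0, 10.0)
    return simulate_displacements(
        presets.homogeneous_phantom(3.0), presets.excitation(1), grid, seed=0
    )


@pytest.fixture(scope="session")
def lesion_field_12():
    """12 kPa spherical lesion in 3 kPa background on the desk grid."""
    return simulate_displacements(
        presets.lesion_phantom(12.0), presets.excitation(1), presets.desk_grid(), seed=0
    )
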