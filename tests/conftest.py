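import numpy as np
import pytest

from hyperflow import (ChannelGeometry, FluidProperties, ParticleProperties,
                       StructuredGrid2D, build_grid,
                       solve_depth_averaged_stokes)

#: the three study flow rates in mL/h and m^3/s
ML_PER_H = 1e-6 / 3600.0
Q_MLH = (7.9e-3, 0.035, 0.265)
Q3 = 0.265 * ML_PER_H


@pytest.fixture(scope="session")
def geom():
    return ChannelGeometry.default()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties.dextran40()


@pytest.fixture(scope="session")
def rbc():
    return ParticleProperties.rbc()


@pytest.fixture(scope="session")
def field_mid(geom, fluid):
    """Mid-resolution hyperbolic-contraction field at the highest flow rate,
    shared across test modules (rescale with ``with_flow_rate`` as needed)."""
    grid = build_grid(geom, 256, 64)
    return solve_depth_averaged_stokes(grid, fluid, Q3)


@pytest.fixture(scope="session")
def field_straight(fluid):
    """Straight-channel solve against the Brinkman closed form."""
    grid = StructuredGrid2D.straight(W=406e-6, h=60e-6, length=1000e-6,
                                     nx=48, ny=64)
    return solve_depth_averaged_stokes(grid, fluid, Q3)
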