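"""Shared fixtures.

Two resolution tiers: a *coarse* tier (100 um lateral, 10 um vertical,
5 um pore cell) that keeps whole-pipeline tests in seconds, and the
*reference* tier at the package defaults (50 um / 5 um / 2.5 um) used where
printed-value comparisons need the default discretization.  Expensive
solves are session-scoped and reused.
"""

import warnings

import numpy as np
import pytest

from moabsim.design import (UL_MIN, evaluate_operating_point, make_setup,
                            sweep_flow_rates)
from moabsim.flow import FlowBC, FluidProperties, solve_stokes_brinkman
from moabsim.geometry import (ChamberSpec, GridSpec, ScaffoldArraySpec,
                              build_chamber_grid)

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*beams inflated.*")

Q5 = 5 * UL_MIN
COARSE_GRID = GridSpec(dx=100e-6, dy=100e-6, dz_fine=10e-6,
                       z_fine_limit=50e-6)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def coarse_setup():
    return make_setup(gridspec=COARSE_GRID, cell_spacing=5e-6)


@pytest.fixture(scope="session")
def coarse_flow(coarse_setup):
    """Chamber flow at 5 uL/min on the coarse tier (cached in the setup)."""
    return coarse_setup.flow_at(Q5)


@pytest.fixture(scope="session")
def coarse_sweep(coarse_setup):
    return sweep_flow_rates([q * UL_MIN for q in (1, 3, 5, 10)], coarse_setup)


@pytest.fixture(scope="session")
def coarse_op5(coarse_sweep):
    return coarse_sweep.point(Q5)


@pytest.fixture(scope="session")
def coarse_oxygen(coarse_setup, coarse_flow):
    """Oxygen solution at 5 uL/min with the reference loading, coarse tier."""
    from moabsim.oxygen import CellLoading, OxygenParams, solve_oxygen
    return solve_oxygen(coarse_setup.labeled, coarse_flow, OxygenParams(),
                        CellLoading())


@pytest.fixture(scope="session")
def ref_setup():
    """Default-resolution setup (50 um lateral, 5 um vertical, 2.5 um cell)."""
    return make_setup()


@pytest.fixture(scope="session")
def ref_op5(ref_setup):
    """The full default-resolution pipeline at the chosen operating point."""
    return evaluate_operating_point(Q5, ref_setup)


@pytest.fixture(scope="session")
def flat_chamber_flow(fluid):
    """Totally flat chamber (no scaffold array) at 5 uL/min.

    Keeps the full 5 um vertical resolution (profile oracles compare
    against the duct series) but the coarse lateral spacing."""
    chamber = ChamberSpec()
    array = ScaffoldArraySpec(n_cols=0)
    labeled = build_chamber_grid(
        chamber, array, GridSpec(dx=100e-6, dy=100e-6, dz_fine=5e-6,
                                 z_fine_limit=50e-6))
    return solve_stokes_brinkman(labeled, fluid, FlowBC(Q=Q5), kappa=1.0)
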