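"""Chamber-scale Stokes--Brinkman solver: oracles, invariants, limits."""

import numpy as np
import pytest

from moabsim._mac import MacGrid, divergence, solve_mac_stokes
from moabsim.design import UL_MIN
from moabsim.flow import (FlowBC, FluidProperties, analytic_plane_poiseuille,
                          analytic_rect_duct, solve_stokes_brinkman,
                          wall_shear_stress)
from moabsim.geometry import (ChamberSpec, GridSpec, ScaffoldArraySpec,
                              build_chamber_grid)
from moabsim.synthetic_data import (make_manufactured_poiseuille,
                                    make_manufactured_stokes)

Q5 = 5 * UL_MIN


class TestFlatChamber:
    def test_mass_conservation_along_the_chamber(self, flat_chamber_flow):
        for x in (1e-3, 3e-3, 5e-3):
            assert flat_chamber_flow.flux_at_x(x) == pytest.approx(
                flat_chamber_flow.Q_sim, rel=1e-3)

    def test_discrete_continuity(self, flat_chamber_flow):
        div = divergence(flat_chamber_flow.mac)
        assert np.abs(div).max() < 1e-10 * flat_chamber_flow.Q_sim

    def test_mid_chamber_profile_matches_duct_series(self, flat_chamber_flow,
                                                     fluid):
        g = flat_chamber_flow.grid
        i = np.searchsorted(g.xf, 3e-3)
        u_num = flat_chamber_flow.mac.u[i, 0, :]          # at the symmetry plane
        u_ex = analytic_rect_duct(Q5, 3e-3, 0.5e-3, fluid, g.yc[0], g.zc)
        assert np.abs(u_num - u_ex).max() / u_ex.max() < 0.02

    def test_floor_shear_matches_analytic(self, flat_chamber_flow, fluid):
        sf = wall_shear_stress(flat_chamber_flow.mac, fluid)
        mid = sf.floor[sf.floor.shape[0] // 2, 0]          # mid-length, mid-width
        tau_series = fluid.mu * analytic_rect_duct(
            Q5, 3e-3, 0.5e-3, fluid, 0.0, 1e-8) / 1e-8
        assert mid == pytest.approx(tau_series, rel=0.05)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            FlowBC(Q=0.0)


class TestBrinkmanChamber:
    def test_mass_conservation(self, coarse_flow):
        for x in (1e-3, 3e-3, 5e-3):
            assert coarse_flow.flux_at_x(x) == pytest.approx(
                coarse_flow.Q_sim, rel=1e-3)
        div = divergence(coarse_flow.mac)
        assert np.abs(div).max() < 1e-10 * coarse_flow.Q_sim

    def test_linearity_in_flow_rate(self, coarse_setup, coarse_flow):
        doubled = coarse_setup.flow_at(2 * Q5)
        assert np.allclose(doubled.mac.u, 2 * coarse_flow.mac.u,
                           rtol=1e-10, atol=1e-16)
        assert np.allclose(doubled.mac.p, 2 * coarse_flow.mac.p,
                           rtol=1e-10, atol=1e-12, equal_nan=True)

    def test_large_kappa_recovers_flat_chamber(self, coarse_setup, fluid):
        open_flow = solve_stokes_brinkman(coarse_setup.labeled, fluid,
                                          FlowBC(Q=Q5), kappa=1.0)
        # the porous block becomes transparent: the solution on the very
        # same grid with the array de-labelled must coincide
        from moabsim.geometry import FLUID as FLUID_LBL
        import copy
        labeled_open = copy.deepcopy(coarse_setup.labeled)
        labeled_open.labels[labeled_open.labels == 1] = FLUID_LBL
        ref = solve_stokes_brinkman(labeled_open, fluid, FlowBC(Q=Q5),
                                    kappa=1.0)
        diff = np.abs(open_flow.mac.u - ref.mac.u).max()
        assert diff < 0.01 * np.abs(ref.mac.u).max()

    def test_small_kappa_drives_darcy_column(self, fluid):
        # 1D porous column: dp/dx -> -(mu/kappa) u exactly in the Darcy limit
        n, L, kappa, u0 = 12, 1e-3, 1e-13, 1e-5
        g = MacGrid(np.linspace(0, L, n + 1), np.linspace(0, 1e-4, 3),
                    np.linspace(0, 1e-4, 3))
        bc = {"x-": {"type": "inflow", "normal": np.full((2, 2), u0)},
              "x+": "outflow", "y-": "symmetry", "y+": "symmetry",
              "z-": "symmetry", "z+": "symmetry"}
        sol = solve_mac_stokes(g, fluid.mu, bc,
                               inv_kappa=np.full(g.shape, 1 / kappa))
        dpdx = (sol.p[-2, 0, 0] - sol.p[1, 0, 0]) / (g.xc[-2] - g.xc[1])
        assert dpdx == pytest.approx(-fluid.mu / kappa * u0, rel=1e-8)

    def test_array_slows_near_floor_flow(self, coarse_flow, flat_chamber_flow):
        # inside the porous block (centre of the fifth scaffold, 15 um up)
        # the superficial velocity drops well below the open-chamber value
        def cell_at(flow, x, y, z):
            g = flow.grid
            return (np.searchsorted(g.xf, x) - 1,
                    np.searchsorted(g.yf, y) - 1,
                    np.searchsorted(g.zf, z) - 1)
        x, y, z = 3.375e-3, 250e-6, 15e-6
        u_in = coarse_flow.mac.u[cell_at(coarse_flow, x, y, z)]
        u_flat = flat_chamber_flow.mac.u[cell_at(flat_chamber_flow, x, y, z)]
        assert u_in < 0.25 * u_flat

    def test_nonconvergence_raises(self, coarse_setup, fluid):
        with pytest.raises(RuntimeError, match="did not converge"):
            solve_stokes_brinkman(coarse_setup.labeled, fluid, FlowBC(Q=Q5),
                                  coarse_setup.kappa, tol=1e-14, maxiter=2)


class TestManufactured:
    def test_poiseuille_reproduced_to_discretization_accuracy(self, fluid):
        prob = make_manufactured_poiseuille(n=12)
        sol = solve_mac_stokes(prob.grid, prob.mu, prob.bc)
        g = prob.grid
        ex = prob.exact["u"](0, 0, g.zc)
        num = sol.u[g.shape[0] // 2, 0, :]
        # cell-centre-sampled inflow parabola carries an O((dz/h)^2) flux
        # excess, so recovery is to discretization accuracy, not rounding
        assert np.abs(num - ex).max() / ex.max() < 1e-2
        sf = wall_shear_stress(sol, FluidProperties(mu=prob.mu))
        # one-sided floor recovery to first order in dz/h: dz = h/12
        assert sf.floor[g.shape[0] // 2, 0] == pytest.approx(
            prob.exact["tau_floor"], rel=0.1)

    def test_stokes_mms_convergence_order(self):
        prob = make_manufactured_stokes(n=8)
        errs = []
        for lev in range(3):
            g = prob.grid
            sol = solve_mac_stokes(g, prob.mu, prob.bc,
                                   body_force=prob.forcing)
            ex = prob.exact["u"](g.xf[:, None, None], g.yc[None, :, None],
                                 g.zc[None, None, :])
            errs.append(float(np.abs(sol.u - ex).max()))
            if lev < 2:
                prob = prob.refined()
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert (orders > 1.5).all()
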