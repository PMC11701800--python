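"""Oxygen transport: kinetics, sinks, conservation, oracles, conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moabsim._adr import solve_adr
from moabsim.design import UL_MIN
from moabsim.oxygen import (CellLoading, OxygenParams, UnitConversion,
                            LineProfile, assemble_sink_field,
                            conc_to_atm_percent, hypoxia_check,
                            line_profile_at_height, michaelis_menten_rate,
                            mixed_cup_outlet, percent_drop, plugflow_oracle,
                            solve_oxygen)
from moabsim.flow import FlowBC, solve_stokes_brinkman
from moabsim.geometry import (ChamberSpec, GridSpec, ScaffoldArraySpec,
                              build_chamber_grid)

PAR = OxygenParams()
CONV = UnitConversion()
Q5 = 5 * UL_MIN


class TestMichaelisMenten:
    def test_half_saturation(self):
        assert michaelis_menten_rate(PAR.Km, PAR) == pytest.approx(
            PAR.Vmax / 2, rel=1e-12)

    def test_zero_and_saturation(self):
        assert michaelis_menten_rate(0.0, PAR) == 0.0
        # evaluated at the inlet concentration: 4e-17 * 0.2/0.20055
        assert michaelis_menten_rate(0.2, PAR) == pytest.approx(3.989e-17,
                                                                rel=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            michaelis_menten_rate(-1e-6, PAR)

    @given(st.floats(0.0, 0.2), st.floats(0.0, 0.2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, c1, c2):
        r1, r2 = michaelis_menten_rate(c1, PAR), michaelis_menten_rate(c2, PAR)
        assert 0.0 <= r1 <= PAR.Vmax
        if c1 <= c2:
            assert r1 <= r2


class TestSinkAssembly:
    def test_saturating_total_consumption(self, coarse_setup):
        # at C >> Km the total sink approaches n_total * Vmax = 2.0e-12 mol/s
        dens = assemble_sink_field(coarse_setup.labeled, CellLoading(), PAR)
        lab = coarse_setup.labeled
        rate_at_C0 = michaelis_menten_rate(PAR.C0, PAR)
        total = (dens["volumetric_density"] * lab.region_volume(1) +
                 dens["areal_density"] * lab.strip_area()) * rate_at_C0
        # half model carries half the cells
        assert 2 * total == pytest.approx(50_000 * PAR.Vmax, rel=3e-3)

    def test_loading_invariants(self):
        with pytest.raises(ValueError):
            CellLoading(n_total=10, n_array=5, n_flat=4)

    def test_zero_region_with_cells_rejected(self):
        lg = build_chamber_grid(ChamberSpec(), ScaffoldArraySpec(n_cols=0),
                                GridSpec(dx=200e-6, dy=150e-6, dz_fine=10e-6))
        with pytest.raises(ValueError, match="porous"):
            assemble_sink_field(lg, CellLoading(), PAR)


class TestOxygenSolve:
    def test_boundedness_and_convergence(self, coarse_oxygen):
        ox = coarse_oxygen
        assert np.nanmin(ox.C) >= 0.0
        assert np.nanmax(ox.C) <= PAR.C0 * (1 + 1e-12)
        assert ox.picard_iterations < 50

    def test_zero_cells_keep_inlet_concentration(self, coarse_setup,
                                                 coarse_flow):
        ox = solve_oxygen(coarse_setup.labeled, coarse_flow, PAR,
                          CellLoading(n_total=0, n_array=0, n_flat=0))
        assert np.nanmax(np.abs(ox.C - PAR.C0)) < 1e-10

    def test_steady_state_mass_balance(self, coarse_setup, coarse_flow,
                                       coarse_oxygen):
        ox = coarse_oxygen
        g = coarse_setup.labeled.grid
        Ax = g.dy[:, None] * g.dz[None, :]
        f_in = float((coarse_flow.mac.u[0] * Ax * PAR.C0).sum())
        f_out = float((coarse_flow.mac.u[-1] * Ax * ox.C[-1]).sum())
        cons = ox.meta["total_consumption_mol_s"]
        assert abs(f_in - f_out - cons) < 0.01 * cons

    def test_mixed_cup_outlet_matches_zeroth_order_balance(self, coarse_oxygen):
        # C >> Km everywhere: outlet = C0 - n_total Vmax / Q = 0.176 mol/m^3
        ox = coarse_oxygen
        expect = PAR.C0 - 50_000 * PAR.Vmax / Q5
        assert mixed_cup_outlet(ox) == pytest.approx(expect, rel=0.02)
        # deep zeroth-order regime: C/Km large everywhere
        assert np.nanmin(ox.C) / PAR.Km > 100

    def test_more_cells_never_raise_concentration(self, coarse_setup,
                                                  coarse_flow):
        ox1 = solve_oxygen(coarse_setup.labeled, coarse_flow, PAR,
                           CellLoading(25_000, 16_000, 9_000))
        ox2 = solve_oxygen(coarse_setup.labeled, coarse_flow, PAR,
                           CellLoading(50_000, 32_000, 18_000))
        assert (ox2.C <= ox1.C + 1e-12).all()

    def test_depletion_monotone_in_the_mixed_cup_sense(self, coarse_setup,
                                                       coarse_flow,
                                                       coarse_oxygen):
        # with sinks only, the flux-weighted cross-section concentration can
        # never rise downstream; the 10 um line itself declines through the
        # array but may recover slightly past its end by vertical mixing
        ox = coarse_oxygen
        g = coarse_setup.labeled.grid
        Ax = g.dy[:, None] * g.dz[None, :]
        cups = []
        for i in range(0, g.shape[0], 5):
            F = coarse_flow.mac.u[i] * Ax
            cups.append(float((F * ox.C[max(i - 1, 0)]).sum() / F.sum()))
        assert (np.diff(cups) <= 1e-9).all()
        prof = line_profile_at_height(ox, 10e-6, "through-array")
        assert prof.C[-1] < prof.C[0]
        # declines through the array's axial extent; in the gaps between
        # consecutive scaffolds the line recovers slightly (richer fluid
        # mixes down), but never by more than a couple percent of C0
        in_arr = (prof.x > 1e-3) & (prof.x < 5e-3)
        assert (np.diff(prof.C[in_arr]) <= 2e-2 * PAR.C0).all()
        assert prof.C[in_arr][-1] < prof.C[in_arr][0]
        flat = line_profile_at_height(ox, 10e-6, "flat-side")
        assert flat.C[-1] > prof.C[-1]      # flat side is less depleted

    def test_well_mixed_limit_matches_plugflow(self, fluid):
        # single-cell-tall flat chamber: the 3D solve collapses onto the
        # 1D plug-flow oracle
        ch = ChamberSpec()
        arr = ScaffoldArraySpec(n_cols=0)
        lg = build_chamber_grid(ch, arr, GridSpec(dx=100e-6, dy=150e-6,
                                                  dz_fine=0.5e-3,
                                                  z_fine_limit=0.5e-3),
                                strip_mode="all_flat")
        flow = solve_stokes_brinkman(lg, fluid, FlowBC(Q=Q5), kappa=1.0)
        loading = CellLoading(50_000, 0, 50_000)
        ox = solve_oxygen(lg, flow, PAR, loading)
        oracle = plugflow_oracle(Q5, PAR, loading)
        assert mixed_cup_outlet(ox) == pytest.approx(oracle.C[-1], rel=0.01)


class TestPlugflowOracle:
    def test_zeroth_order_closed_form(self):
        prof = plugflow_oracle(Q5, PAR, CellLoading())
        assert prof.C[-1] == pytest.approx(0.176, rel=1e-3)

    def test_no_cells_flat_profile(self):
        prof = plugflow_oracle(Q5, PAR, CellLoading(0, 0, 0))
        assert np.allclose(prof.C, PAR.C0)

    def test_halving_flow_doubles_the_drop(self):
        d1 = PAR.C0 - plugflow_oracle(Q5, PAR, CellLoading()).C[-1]
        d2 = PAR.C0 - plugflow_oracle(Q5 / 2, PAR, CellLoading()).C[-1]
        assert d2 == pytest.approx(2 * d1, rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            plugflow_oracle(0.0, PAR, CellLoading())
        with pytest.raises(ValueError):
            plugflow_oracle(Q5, PAR, CellLoading(), n_segments=5)


class TestUnitConversion:
    def test_drop_reconciles_concentration_and_percent_scales(self):
        # 0.2 -> 0.14 mol/m^3 with the 18.6 % inlet anchor is 5.58 points
        prof = LineProfile(x=np.array([0.0, 6e-3]),
                           C=np.array([0.2, 0.14]), z=10e-6,
                           path="through-array", y=250e-6)
        assert percent_drop(prof, CONV) == pytest.approx(5.58, abs=0.01)
        assert percent_drop(prof, CONV, "relative") == pytest.approx(30.0)

    def test_two_point_drop_inverse(self):
        prof = LineProfile(x=np.array([0.0, 6e-3]),
                           C=np.array([0.2, 0.1785]), z=10e-6,
                           path="through-array", y=250e-6)
        assert percent_drop(prof, CONV) == pytest.approx(2.0, abs=0.01)

    def test_flat_profile_zero_drop(self):
        prof = LineProfile(x=np.linspace(0, 6e-3, 10),
                           C=np.full(10, 0.2), z=10e-6, path="x", y=0.0)
        assert percent_drop(prof, CONV) == 0.0
        assert percent_drop(prof, CONV, "relative") == 0.0

    def test_percent_anchors(self):
        assert conc_to_atm_percent(0.14, CONV) == pytest.approx(13.02, abs=0.01)
        assert conc_to_atm_percent(0.0, CONV) == 0.0
        # hypoxia threshold back in concentration units
        assert CONV.hypoxia_percent / CONV.k == pytest.approx(0.010753,
                                                              rel=1e-3)


class TestAdrScheme:
    def test_manufactured_convergence_order(self):
        from moabsim.synthetic_data import make_manufactured_adr
        prob = make_manufactured_adr(n=24)
        errs = []
        for lev in range(3):
            g = prob.grid
            src = prob.exact["source"](g.xc)[:, None, None] * np.ones(g.shape)
            C = solve_adr(g, prob.face_velocity, prob.D, prob.bc, source=src)
            ex = prob.exact["C"](g.xc)[:, None, None] * np.ones(g.shape)
            errs.append(float(np.nanmax(np.abs(C - ex))))
            if lev < 2:
                prob = prob.refined()
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert (orders > 0.9).all() and (orders < 2.1).all()

    def test_pure_diffusion_linear_field_exact(self):
        from moabsim._mac import MacGrid
        n = 10
        g = MacGrid(np.linspace(0, 1e-3, n + 1), np.linspace(0, 1e-4, 3),
                    np.linspace(0, 1e-4, 3))
        fu = (np.zeros((n + 1, 2, 2)), np.zeros((n, 3, 2)),
              np.zeros((n, 2, 3)))
        bc = {"x-": {"type": "dirichlet", "value": 0.2},
              "x+": {"type": "dirichlet", "value": 0.1}}
        C = solve_adr(g, fu, 2e-9, bc)
        ex = 0.2 + (0.1 - 0.2) * g.xc / 1e-3
        assert np.abs(C[:, 0, 0] - ex).max() < 1e-12
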