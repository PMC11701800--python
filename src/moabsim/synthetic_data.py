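"""Self-contained inputs: the reference configuration, manufactured-solution
verification problems and randomized property-test fixtures.

Nothing here touches the network or external files; every fixture is built
in memory from printed constants or from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mac import MacGrid

__all__ = ["reference_config", "random_config", "ManufacturedProblem",
           "make_manufactured_stokes", "make_manufactured_poiseuille",
           "make_manufactured_adr"]


def reference_config() -> dict:
    """The reference operating configuration of the microscaffold MOAB.

    6 x 3 x 0.5 mm chamber with 0.76 mm inlet/outlet ports; a 2 x 8 array
    of 500 x 500 x 40 um microstructures with 50 x 50 x 20 um pores framed
    by 4.9 x 1.0 um beams; medium as water at 37 C; oxygen kinetics
    D = 2e-9 m^2/s, C0 = 0.2 mol/m^3, Vmax = 4e-17 mol/s per cell,
    Km = 5.5e-4 mol/m^3; 50,000 cells split 32,000 (array) / 18,000 (flat
    strip); candidate flow rates 1/3/5/10 uL/min; physiological windows
    0.1--5 um/s and 0.1--10 mPa; hypoxia below 1 %, dermal normoxia 13 %.
    """
    return {
        "chamber": {
            "length_x": 6e-3, "width_y": 3e-3, "height_z": 0.5e-3,
            "inlet_diameter": 0.76e-3, "inlet_height": 3e-3,
            "half_model": True,
        },
        "microstructure": {
            "footprint_x": 500e-6, "footprint_y": 500e-6, "height": 40e-6,
            "pore_x": 50e-6, "pore_y": 50e-6, "pore_z": 20e-6,
            "beam_axial": 4.9e-6, "beam_lateral": 1.0e-6,
        },
        "array": {
            "n_rows": 2, "n_cols": 8, "pitch_x": None,
            "lateral_offset": 250e-6,
        },
        "grid": {
            "dx": 50e-6, "dy": 50e-6, "dz_fine": 5e-6,
            "z_fine_limit": 50e-6, "growth": 1.2,
        },
        "unit_cell": {
            "spacing": 2.5e-6, "near_surface_offset": 2.5e-6,
        },
        "fluid": {"mu": 6.9e-4, "rho": 993.0, "temperature": 37.0},
        "oxygen": {"D": 2e-9, "C0": 0.2, "Vmax": 4e-17, "Km": 5.5e-4},
        "cells": {"n_total": 50_000, "n_array": 32_000, "n_flat": 18_000},
        "conversion": {"percent_at_C0": 18.6, "hypoxia_percent": 1.0,
                       "normoxia_percent": 13.0},
        "ranges": {"velocity_min": 0.1e-6, "velocity_max": 5e-6,
                   "velocity_max_broad": 10e-6,
                   "wss_min": 0.1e-3, "wss_max": 10e-3},
        "sweep": {"rates_ul_min": [1.0, 3.0, 5.0, 10.0], "rule": "largest"},
        "solver": {"tol": 1e-11, "maxiter": 10000,
                   "picard_tol": 1e-8, "picard_maxiter": 50},
    }


def random_config(seed: int) -> dict:
    """Validity-preserving random perturbation of the reference config.

    Chamber and microstructure dimensions move by up to +-20 %, kinetic
    parameters by up to +-50 %; pore and footprint sizes scale together so
    the pores still tile the footprint exactly.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    cfg = reference_config()

    def dim(x, frac=0.2):
        return float(x * (1.0 + rng.uniform(-frac, frac)))

    ch = cfg["chamber"]
    ch["length_x"] = dim(ch["length_x"])
    ch["width_y"] = dim(ch["width_y"])
    ch["height_z"] = dim(ch["height_z"])
    ch["inlet_diameter"] = dim(ch["inlet_diameter"])

    ms = cfg["microstructure"]
    sxy = 1.0 + rng.uniform(-0.2, 0.2)       # horizontal pore/footprint scale
    sz = 1.0 + rng.uniform(-0.2, 0.2)
    for k in ("footprint_x", "footprint_y", "pore_x", "pore_y"):
        ms[k] = float(ms[k] * sxy)
    ms["height"] = float(ms["height"] * sz)
    ms["pore_z"] = float(ms["pore_z"] * sz)
    ms["beam_axial"] = dim(ms["beam_axial"])
    ms["beam_lateral"] = dim(ms["beam_lateral"])

    cfg["array"]["lateral_offset"] = float(ms["footprint_y"] / 2.0)

    fl = cfg["fluid"]
    fl["mu"] = dim(fl["mu"])
    fl["rho"] = dim(fl["rho"])

    ox = cfg["oxygen"]
    for k in ("D", "C0", "Vmax", "Km"):
        ox[k] = dim(ox[k], 0.5)
    cfg["conversion"]["percent_at_C0"] = float(
        cfg["conversion"]["percent_at_C0"])

    n_tot = int(rng.integers(10_000, 100_000))
    n_arr = int(round(n_tot * rng.uniform(0.4, 0.8)))
    cfg["cells"] = {"n_total": n_tot, "n_array": n_arr,
                    "n_flat": n_tot - n_arr}
    cfg["_seed"] = int(seed)
    return cfg


# ---------------------------------------------------------------------------
# manufactured solutions
# ---------------------------------------------------------------------------

@dataclass
class ManufacturedProblem:
    """A closed-form field plus the forcing that makes it an exact steady
    solution, with the boundary data the solvers understand."""

    kind: str                       # "stokes" | "adr"
    grid: MacGrid
    exact: dict                     # callables: u,v,w,p or C
    forcing: object                 # callable or arrays
    bc: dict
    mu: float = 6.9e-4
    D: float = 2e-9
    face_velocity: tuple | None = None     # for adr problems
    expected_order: float = 2.0
    meta: dict = field(default_factory=dict)

    def refined(self, factor: int = 2) -> "ManufacturedProblem":
        g = self.grid
        def ref(f):
            out = [f[0]]
            for a, b in zip(f[:-1], f[1:]):
                out.extend(np.linspace(a, b, factor + 1)[1:])
            return np.asarray(out)
        g2 = MacGrid(ref(g.xf), ref(g.yf), ref(g.zf))
        p2 = ManufacturedProblem(kind=self.kind, grid=g2, exact=self.exact,
                                 forcing=self.forcing, bc=self.bc, mu=self.mu,
                                 D=self.D, expected_order=self.expected_order,
                                 meta=dict(self.meta))
        if self.face_velocity is not None and "u0" in self.meta:
            shp = g2.shape
            p2.face_velocity = (
                np.full((shp[0] + 1, shp[1], shp[2]), self.meta["u0"]),
                np.zeros((shp[0], shp[1] + 1, shp[2])),
                np.zeros((shp[0], shp[1], shp[2] + 1)))
        if isinstance(self.bc.get("x-"), dict) and \
                self.bc["x-"].get("type") == "inflow" and "u" in self.exact:
            prof = self.exact["u"](0.0, g2.yc[:, None], g2.zc[None, :])
            p2.bc = dict(self.bc, **{"x-": {"type": "inflow",
                                            "normal": prof}})
        return p2


def make_manufactured_stokes(n: int = 16, L: float = 1e-3,
                             mu: float = 6.9e-4, U0: float = 1e-4,
                             P0: float = 1.0) -> ManufacturedProblem:
    """Divergence-free trigonometric Stokes field on an L^3 box.

    u = U0 sin(kx) cos(ky), v = -U0 cos(kx) sin(ky), w = 0,
    p = P0 cos(kx) cos(ky), k = pi/L; Dirichlet x/y walls, symmetry in z.
    The forcing -mu lap u + grad p is supplied in closed form; the MAC
    discretization converges at second order to this smooth field.
    """
    k = np.pi / L
    grid = MacGrid(np.linspace(0, L, n + 1), np.linspace(0, L, n + 1),
                   np.linspace(0, L, max(n // 4, 2) + 1))

    exact = {
        "u": lambda x, y, z: U0 * np.sin(k * x) * np.cos(k * y) + 0 * z,
        "v": lambda x, y, z: -U0 * np.cos(k * x) * np.sin(k * y) + 0 * z,
        "w": lambda x, y, z: 0.0 * x * y * z,
        "p": lambda x, y, z: P0 * np.cos(k * x) * np.cos(k * y) + 0 * z,
    }

    def forcing(X, Y, Z):
        # f = grad p - mu lap u for the chosen fields
        fx = (2 * mu * k ** 2 * U0 - P0 * k) * np.sin(k * X) * np.cos(k * Y)
        fy = -(2 * mu * k ** 2 * U0 + P0 * k) * np.cos(k * X) * np.sin(k * Y)
        return (fx, fy, np.zeros_like(fx))

    def dirichlet(x, y, z):
        return (exact["u"](x, y, z), exact["v"](x, y, z), exact["w"](x, y, z))

    bc = {"x-": {"type": "dirichlet", "values": dirichlet},
          "x+": {"type": "dirichlet", "values": dirichlet},
          "y-": {"type": "dirichlet", "values": dirichlet},
          "y+": {"type": "dirichlet", "values": dirichlet},
          "z-": "symmetry", "z+": "symmetry"}
    return ManufacturedProblem(kind="stokes", grid=grid, exact=exact,
                               forcing=forcing, bc=bc, mu=mu,
                               expected_order=2.0,
                               meta={"U0": U0, "P0": P0, "k": k})


def make_manufactured_poiseuille(Q: float = 8.3333e-11, width: float = 3e-3,
                                 height: float = 0.5e-3, length: float = 2e-3,
                                 mu: float = 6.9e-4,
                                 n: int = 16) -> ManufacturedProblem:
    """Plane Poiseuille channel as a manufactured problem (no forcing).

    The inflow carries the exact parabola; laterally the channel is
    unbounded (symmetry).  The MAC scheme reproduces the quadratic profile
    to discretization accuracy on any grid that resolves it.
    """
    Um = Q / (width * height)

    def ux(z):
        return 6.0 * Um * (z / height) * (1.0 - z / height)

    grid = MacGrid(np.linspace(0, length, n + 1),
                   np.linspace(0, width / 8, 3),
                   np.linspace(0, height, n + 1))
    prof = np.tile(ux(grid.zc), (grid.shape[1], 1))
    exact = {
        "u": lambda x, y, z: ux(z) + 0 * x + 0 * y,
        "w": lambda x, y, z: 0 * x * y * z,
        "v": lambda x, y, z: 0 * x * y * z,
        "tau_floor": 6.0 * mu * Q / (width * height ** 2),
    }
    bc = {"x-": {"type": "inflow", "normal": prof}, "x+": "outflow",
          "y-": "symmetry", "y+": "symmetry", "z-": "wall", "z+": "wall"}
    return ManufacturedProblem(kind="stokes", grid=grid, exact=exact,
                               forcing=None, bc=bc, mu=mu,
                               expected_order=2.0,
                               meta={"Q": Q, "width": width, "height": height})


def make_manufactured_adr(n: int = 32, Pe: float = 10.0, L: float = 6e-3,
                          D: float = 2e-9, C0: float = 0.2) -> ManufacturedProblem:
    """1D cosine concentration field advected at cell Peclet ~ Pe/n.

    C(x) = C0 (0.6 + 0.4 cos(pi x / L)) with uniform velocity u = Pe D / L;
    the closed-form source u dC/dx - D d2C/dx2 makes it exact.  dC/dx
    vanishes at the outlet, so the advective-outflow condition is
    consistent; the upwind scheme converges at first order.
    """
    u0 = Pe * D / L
    k = np.pi / L
    grid = MacGrid(np.linspace(0, L, n + 1), np.linspace(0, L / 8, 3),
                   np.linspace(0, L / 8, 3))

    def C_exact(x):
        return C0 * (0.6 + 0.4 * np.cos(k * x))

    def source_1d(x):
        return (u0 * (-C0 * 0.4 * k * np.sin(k * x))
                - D * (-C0 * 0.4 * k * k * np.cos(k * x)))

    shp = grid.shape
    fu = (np.full((shp[0] + 1, shp[1], shp[2]), u0),
          np.zeros((shp[0], shp[1] + 1, shp[2])),
          np.zeros((shp[0], shp[1], shp[2] + 1)))
    bc = {"x-": {"type": "dirichlet", "value": float(C_exact(0.0))},
          "x+": "outflow"}
    prob = ManufacturedProblem(kind="adr", grid=grid,
                               exact={"C": C_exact, "source": source_1d},
                               forcing=source_1d, bc=bc, D=D,
                               face_velocity=fu, expected_order=1.0,
                               meta={"Pe": Pe, "u0": u0, "C0": C0})
    return prob
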