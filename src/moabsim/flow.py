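"""Creeping flow through the chamber and the resolved pore-scale unit cell.

At the chamber scale the microscaffold array is represented as a Brinkman
porous block: ``0 = -grad p + mu lap u - (mu/kappa) u`` inside the array and
plain Stokes outside, with the permeability ``kappa`` estimated from the
beam-lattice solid fraction.  At the pore scale a single pore column with
resolved (voxelized) beams is solved under a uniform body force and rescaled
— creeping flow is linear — so that its volume-averaged velocity matches the
local superficial velocity of the chamber solution (one-way nesting).

Wall shear stress follows the convention tau_zx = mu * du_x/dz evaluated
one-sided into the fluid; positive for flow in +x over a floor.  Reported
tables use mPa and um/s; everything internal is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mac import MacGrid, MacStokesSolution, divergence, solve_mac_stokes
from .geometry import (POROUS_ARRAY, LabeledGrid, ProbeSet, UnitCellGrid)

__all__ = [
    "FluidProperties", "FlowBC", "FlowSolution", "ShearStressField",
    "analytic_plane_poiseuille", "analytic_rect_duct", "estimate_permeability",
    "solve_stokes_brinkman", "solve_unit_cell_stokes", "wall_shear_stress",
    "probe_velocity", "beam_averaged_wss", "nested_pore_metrics",
    "near_surface_velocity", "superficial_velocity_at", "floor_tau_at",
    "mean_cell_velocity", "reynolds_number",
]

KAPPA_CAP = 1.0  # m^2; returned for vanishing solid fraction (no obstruction)


@dataclass(frozen=True)
class FluidProperties:
    """Culture medium, approximated as water at 37 C."""

    mu: float = 6.9e-4        # Pa s
    rho: float = 993.0        # kg/m^3
    temperature: float = 37.0  # C, informational

    def __post_init__(self):
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be > 0")


@dataclass(frozen=True)
class FlowBC:
    """Perfusion boundary conditions: imposed flow rate, open outlet."""

    Q: float                  # m^3/s, full-chamber flow rate
    p_out: float = 0.0        # Pa
    symmetry: bool = True     # y = 0 symmetry plane (half model)

    def __post_init__(self):
        if self.Q <= 0:
            raise ValueError("flow rate must be > 0")
        if self.p_out != 0.0:
            raise ValueError("outlet pressure is fixed at 0 Pa")


@dataclass
class FlowSolution:
    """Chamber-scale flow field with bookkeeping."""

    mac: MacStokesSolution
    labeled: LabeledGrid
    fluid: FluidProperties
    Q: float                  # full-chamber flow rate, m^3/s
    kappa: float
    reynolds: float
    meta: dict = field(default_factory=dict)

    @property
    def grid(self) -> MacGrid:
        return self.mac.grid

    @property
    def Q_sim(self) -> float:
        """Flow rate through the simulated (possibly half) domain."""
        return self.Q / 2.0 if self.labeled.chamber.half_model else self.Q

    def scaled(self, Q_new: float) -> "FlowSolution":
        """Exact rescaling to another flow rate (Stokes linearity)."""
        f = Q_new / self.Q
        return FlowSolution(mac=self.mac.scaled(f), labeled=self.labeled,
                            fluid=self.fluid, Q=Q_new, kappa=self.kappa,
                            reynolds=self.reynolds * f,
                            meta=dict(self.meta, scaled_from=self.Q))

    def flux_at_x(self, x: float) -> float:
        """Volumetric flux (m^3/s) through the cross-section nearest x."""
        g = self.grid
        i = int(np.argmin(np.abs(g.xf - x)))
        Ax = g.dy[:, None] * g.dz[None, :]
        return float((self.mac.u[i] * Ax).sum())


@dataclass
class ShearStressField:
    """tau_zx sampled on horizontal solid surfaces (Pa)."""

    grid: MacGrid
    floor: np.ndarray                     # (nx, ny) tau_zx on the chamber floor
    beam_top: dict = field(default_factory=dict)   # (i,j,k)-> tau on solid-top faces
    mu: float = 0.0


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def analytic_plane_poiseuille(Q: float, width: float, height: float,
                              fluid: FluidProperties, z) -> dict:
    """Plane Poiseuille flow between parallel plates spanning ``width``.

    u_x(z) = 6 (Q / (w h)) (z/h)(1 - z/h);  tau_floor = 6 mu Q / (w h^2).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > height):
        raise ValueError("z outside the channel")
    Um = Q / (width * height)
    u = 6.0 * Um * (z / height) * (1.0 - z / height)
    tau = 6.0 * fluid.mu * Q / (width * height ** 2)
    return {"u_x": u if u.ndim else float(u), "tau_floor": float(tau)}


def analytic_rect_duct(Q: float, width: float, height: float,
                       fluid: FluidProperties, y, z, terms: int = 50):
    """Fully developed laminar flow in a rectangular duct (Fourier series).

    ``y`` is measured from the duct centreline (|y| <= width/2), ``z`` from
    the floor.  The series is renormalized so its cross-section integral is
    exactly ``Q`` (trapezoid quadrature on a fine grid), which removes the
    truncation-error dependence of the flux.
    """
    if terms < 1:
        raise ValueError("series truncation order must be >= 1")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(y) > width / 2 + 1e-15) or np.any(z < -1e-15) or \
            np.any(z > height + 1e-15):
        raise ValueError("(y, z) outside the duct cross-section")

    def shape(yv, zv):
        acc = np.zeros(np.broadcast(yv, zv).shape)
        for m in range(1, 2 * terms, 2):
            km = m * np.pi / height
            # cosh(km y)/cosh(km w/2) in overflow-safe form (|y| <= w/2)
            a = km * np.abs(yv)
            b = km * width / 2.0
            ratio = (np.exp(a - b) + np.exp(-a - b)) / (1.0 + np.exp(-2.0 * b))
            acc += (1.0 / m ** 3) * np.sin(km * zv) * (1.0 - ratio)
        return acc

    # normalize by numerically integrating the same truncated series
    ny, nz = 201, 201
    yg = np.linspace(-width / 2, width / 2, ny)
    zg = np.linspace(0, height, nz)
    F = shape(yg[:, None], zg[None, :])
    flux = np.trapezoid(np.trapezoid(F, zg, axis=1), yg)
    u = shape(y, z) * (Q / flux)
    return u if u.ndim else float(u)


def reynolds_number(Q: float, chamber_width: float, chamber_height: float,
                    fluid: FluidProperties) -> float:
    """Re = rho u_mean h / mu with u_mean = Q / (w h)."""
    um = Q / (chamber_width * chamber_height)
    return fluid.rho * um * chamber_height / fluid.mu


# ---------------------------------------------------------------------------
# permeability of the beam lattice
# ---------------------------------------------------------------------------

def estimate_permeability(metrics: dict) -> float:
    """Permeability (m^2) of the sparse beam lattice.

    Uses the Jackson--James correlation for three-dimensional fibre webs,
    kappa = (3 r^2 / (20 phi)) (-ln phi - 0.931), with phi the solid
    fraction and r the radius of the equal-area circle of the elliptical
    beam cross-section.  Valid for dilute lattices; rejected for
    phi >= 0.5.  A vanishing solid fraction returns the documented large
    finite cap instead of infinity.
    """
    phi = float(metrics["solid_fraction"])
    r = float(metrics["fiber_radius"])
    if phi >= 0.5:
        raise ValueError("fiber-web permeability correlation invalid for "
                         "solid fraction >= 0.5")
    if phi <= 0 or r <= 0:
        return KAPPA_CAP
    kappa = (3.0 * r ** 2 / (20.0 * phi)) * (-np.log(phi) - 0.931)
    if kappa <= 0:       # extremely dense edge of validity
        raise ValueError("correlation returned non-positive permeability")
    return float(min(kappa, KAPPA_CAP))


# ---------------------------------------------------------------------------
# chamber-scale solve
# ---------------------------------------------------------------------------

def solve_stokes_brinkman(labeled: LabeledGrid, fluid: FluidProperties,
                          bc: FlowBC, kappa: float,
                          tol: float = 1e-11, maxiter: int = 10000) -> FlowSolution:
    """Steady creeping flow through the labeled chamber grid.

    Inlet: fully developed rectangular-duct profile scaled so the discrete
    face flux equals the imposed flow rate; outlet p = 0 with zero normal
    gradient; y = 0 symmetry in the half model; no-slip walls elsewhere.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    chamber = labeled.chamber
    g = labeled.grid
    nx, ny, nz = g.shape
    Q_sim = bc.Q / 2.0 if chamber.half_model else bc.Q

    # fully developed duct profile over the full chamber cross-section,
    # evaluated at inlet face centres; g.yc is already the distance from the
    # centreline in the half model and the signed offset in the full model
    prof = analytic_rect_duct(bc.Q, chamber.width_y, chamber.height_z, fluid,
                              g.yc[:, None], g.zc[None, :])
    # rescale so the *discrete* inlet flux equals Q_sim exactly
    Ax = g.dy[:, None] * g.dz[None, :]
    prof = prof * (Q_sim / float((prof * Ax).sum()))

    invk = np.where(labeled.labels == POROUS_ARRAY, 1.0 / kappa, 0.0)
    solid = labeled.hydrodynamic_solid()
    bcs = {
        "x-": {"type": "inflow", "normal": prof},
        "x+": "outflow",
        "y-": "symmetry" if chamber.half_model else "wall",
        "y+": "wall",
        "z-": "wall",
        "z+": "wall",
    }
    mac = solve_mac_stokes(g, fluid.mu, bcs, solid=solid, inv_kappa=invk,
                           tol=tol, maxiter=maxiter)
    Re = reynolds_number(bc.Q, chamber.width_y, chamber.height_z, fluid)
    meta = {"kappa": kappa, "inlet_profile": "rect_duct",
            "max_div": float(np.abs(divergence(mac)).max())}
    if Re > 1.0:
        import warnings
        warnings.warn(f"Re = {Re:.2f} > 1: creeping-flow assumption strained",
                      RuntimeWarning, stacklevel=2)
    return FlowSolution(mac=mac, labeled=labeled, fluid=fluid, Q=bc.Q,
                        kappa=kappa, reynolds=Re, meta=meta)


# ---------------------------------------------------------------------------
# resolved unit-cell solve
# ---------------------------------------------------------------------------

def solve_unit_cell_stokes(cell: UnitCellGrid, superficial_velocity: float,
                           fluid: FluidProperties,
                           tol: float = 1e-11, maxiter: int = 10000) -> MacStokesSolution:
    """Resolved pore-scale flow around the beams of one pore column.

    The cell is periodic along the flow (x), periodic or symmetric along y,
    no-slip floor and beams, free-slip (symmetry) top.  It is driven by a
    uniform x body force and, by linearity, rescaled so the volume-averaged
    u_x over the cell equals ``superficial_velocity``.
    """
    lat = "periodic" if cell.lateral == "periodic" else "symmetry"
    top = "wall" if cell.meta.get("top") == "wall" else "symmetry"
    bcs = {"x-": "periodic", "x+": "periodic",
           "y-": lat, "y+": lat,
           "z-": "wall", "z+": top}
    mac = solve_mac_stokes(cell.grid, fluid.mu, bcs, solid=cell.solid,
                           body_force=(1.0, 0.0, 0.0), tol=tol,
                           maxiter=maxiter)
    mean_u = mean_cell_velocity(mac)
    if superficial_velocity == 0.0 or mean_u == 0.0:
        return mac.scaled(0.0) if superficial_velocity == 0 else mac
    return mac.scaled(superficial_velocity / mean_u)


def mean_cell_velocity(mac: MacStokesSolution) -> float:
    """Volume-averaged u_x over the whole cell (superficial velocity)."""
    g = mac.grid
    uc = mac.cell_velocity()[..., 0]
    V = g.cell_volumes()
    uc = np.where(mac.solid, 0.0, uc)
    return float((uc * V).sum() / V.sum())


# ---------------------------------------------------------------------------
# wall shear stress
# ---------------------------------------------------------------------------

def wall_shear_stress(mac: MacStokesSolution, fluid: FluidProperties) -> ShearStressField:
    """tau_zx on horizontal solid surfaces, one-sided into the fluid.

    Covers the chamber floor (z = 0) and, where resolved solids exist, the
    top faces of solid voxels (beam segments).
    """
    g = mac.grid
    nx, ny, nz = g.shape
    ux_cell = 0.5 * (mac.u[1:, :, :] + mac.u[:-1, :, :]) \
        if mac.u.shape[0] == nx + 1 else 0.5 * (mac.u + np.roll(mac.u, -1, axis=0))
    # floor: du/dz ~ u(first cell centre)/(dz0/2)
    floor = fluid.mu * ux_cell[:, :, 0] / (g.dz[0] / 2.0)
    floor = np.where(mac.solid[:, :, 0], np.nan, floor)
    beam = {}
    if mac.solid.any():
        sol = mac.solid
        for (i, j, k) in zip(*np.where(sol)):
            if k + 1 < nz and not sol[i, j, k + 1]:
                beam[(i, j, k)] = float(
                    fluid.mu * ux_cell[i, j, k + 1] / (g.dz[k + 1] / 2.0))
    return ShearStressField(grid=g, floor=floor, beam_top=beam, mu=fluid.mu)


def floor_tau_at(sf: ShearStressField, x: float, y: float) -> float:
    g = sf.grid
    i = int(np.clip(np.searchsorted(g.xf, x) - 1, 0, g.shape[0] - 1))
    j = int(np.clip(np.searchsorted(g.yf, y) - 1, 0, g.shape[1] - 1))
    val = sf.floor[i, j]
    if np.isnan(val):
        raise ValueError("requested shear on a non-fluid floor voxel")
    return float(val)


# ---------------------------------------------------------------------------
# interpolation and probe tables
# ---------------------------------------------------------------------------

def _trilinear(grid: MacGrid, field3: np.ndarray, x: float, y: float,
               z: float) -> float:
    """Trilinear interpolation of a cell-centred field (clamped at edges)."""
    out = field3
    coords = (grid.xc, grid.yc, grid.zc)
    pt = (x, y, z)
    idx = []
    wts = []
    for c, p in zip(coords, pt):
        i = int(np.clip(np.searchsorted(c, p) - 1, 0, c.size - 2)) \
            if c.size > 1 else 0
        if c.size == 1:
            idx.append((0, 0))
            wts.append((1.0, 0.0))
            continue
        t = (p - c[i]) / (c[i + 1] - c[i])
        t = min(max(t, 0.0), 1.0)
        idx.append((i, i + 1))
        wts.append((1.0 - t, t))
    val = 0.0
    for di in range(2):
        for dj in range(2):
            for dk in range(2):
                val += (wts[0][di] * wts[1][dj] * wts[2][dk]
                        * out[idx[0][di], idx[1][dj], idx[2][dk]])
    return float(val)


def probe_velocity(sol: FlowSolution, probes: ProbeSet) -> pd.DataFrame:
    """Point velocities at the pore-centre probes (chamber-scale field).

    Returns a table keyed by (microstructure, pore, height_um) with u_x and
    |u| in um/s.  Probes that land in a resolved solid voxel are flagged and
    reported from the nearest fluid voxel.
    """
    g = sol.grid
    uvw = sol.mac.cell_velocity()
    rows = []
    for p in probes.velocity:
        if not (g.xf[0] <= p.x <= g.xf[-1] and g.yf[0] <= p.y <= g.yf[-1]
                and g.zf[0] <= p.z <= g.zf[-1]):
            raise ValueError(f"probe {p} outside the domain")
        i = int(np.clip(np.searchsorted(g.xf, p.x) - 1, 0, g.shape[0] - 1))
        j = int(np.clip(np.searchsorted(g.yf, p.y) - 1, 0, g.shape[1] - 1))
        k = int(np.clip(np.searchsorted(g.zf, p.z) - 1, 0, g.shape[2] - 1))
        flagged = bool(sol.mac.solid[i, j, k])
        comps = [_trilinear(g, uvw[..., c], p.x, p.y, p.z) for c in range(3)]
        rows.append({
            "microstructure": p.microstructure, "pore": p.pore,
            "height_um": p.height_um,
            "u_x_um_s": comps[0] * 1e6,
            "u_mag_um_s": float(np.linalg.norm(comps)) * 1e6,
            "in_solid": flagged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way nesting: chamber -> unit cell, probe metrics
# ---------------------------------------------------------------------------

def superficial_velocity_at(sol: FlowSolution, x: float, y: float,
                            z_top: float) -> float:
    """Depth-averaged u_x of the chamber solution over z in [0, z_top]."""
    g = sol.grid
    zs = np.linspace(0, z_top, 33)
    uc = sol.mac.cell_velocity()[..., 0]
    vals = [_trilinear(g, uc, x, y, z) for z in zs]
    return float(np.trapezoid(vals, zs) / z_top)


def _beam_layer_voxels(cell: UnitCellGrid, height_um: float) -> tuple[float, list[int]]:
    """Rung voxel layers framing the given probe height: 10 um -> the
    floor-level beams, 20 um -> the mid plane, 40 um -> the top plane."""
    zl = min(cell.beam_layer_z, key=lambda v: abs(v - height_um * 1e-6))
    lv = cell.meta.get("layer_voxels", {})
    ks = lv.get(zl, [])
    if not ks:
        g = cell.grid
        ks = [0 if zl == 0 else int(np.searchsorted(g.zf, zl - 1e-12)) - 1]
    return zl, sorted(ks)


def beam_averaged_wss(cell: UnitCellGrid, cell_sol: MacStokesSolution,
                      fluid: FluidProperties, height_um: float) -> float:
    """Mean tau_zx (Pa) along the outlet-side beam segments of the pore at
    one probing height.

    The outlet-side pore face is the downstream (x-periodic image) face; its
    framing segments at a given height are the beam voxels of the y-running
    rung at that layer (plus the post corners they include).  tau is
    evaluated one-sided on the exposed top face of the rung.
    """
    sf = wall_shear_stress(cell_sol, fluid)
    _, ks = _beam_layer_voxels(cell, height_um)
    vals = [t for (i, j, kk), t in sf.beam_top.items()
            if kk in ks and i == 0]         # the y-running rung at x = 0 (= pore face)
    if not vals:
        raise ValueError(f"no beam samples at height {height_um} um")
    return float(np.mean(vals))


def near_surface_velocity(cell: UnitCellGrid, cell_sol: MacStokesSolution,
                          height_um: float, offset: float = 2.5e-6) -> float:
    """Max |u| sampled ``offset`` above the beam surfaces framing the pore
    at one probing height (the fluid layer where adherent cells sit)."""
    g = cell.grid
    uvw = cell_sol.cell_velocity()
    umag = np.linalg.norm(np.where(cell_sol.solid[..., None], 0.0, uvw), axis=-1)
    _, ks = _beam_layer_voxels(cell, height_um)
    ktop = ks[-1]
    best = 0.0
    for (i, j, kk) in zip(*np.where(cell_sol.solid)):
        if kk != ktop or (kk + 1 < g.shape[2] and cell_sol.solid[i, j, kk + 1]):
            continue
        x, y = g.xc[i], g.yc[j]
        z = min(g.zf[kk + 1] + offset, g.zf[-1] - 1e-12)
        best = max(best, _trilinear(g, umag, x, y, z))
    return float(best)


def nested_pore_metrics(sol: FlowSolution, probes: ProbeSet,
                        cell: UnitCellGrid, fluid: FluidProperties,
                        near_surface_offset: float = 2.5e-6,
                        base: MacStokesSolution | None = None) -> pd.DataFrame:
    """Pore-scale probe table via one-way nesting.

    For every probed (microstructure, pore) the unit cell is rescaled to the
    chamber's local superficial velocity; per height the table reports the
    pore-centre point velocity, the near-surface velocity (``offset`` above
    the framing beams) and the outlet-side beam-averaged wall shear stress.
    ``base`` may carry a precomputed unit-cell solution (any scaling).
    """
    if base is None:
        base = solve_unit_cell_stokes(cell, 1.0, fluid)
    mean_base = mean_cell_velocity(base)
    z_top = cell.grid.zf[-1]
    rows = []
    seen = {}
    for p in probes.velocity:
        key = (p.microstructure, p.pore)
        if key not in seen:
            seen[key] = superficial_velocity_at(sol, p.x, p.y, z_top)
        s = seen[key]
        f = s / mean_base if mean_base else 0.0
        scaled = base.scaled(f)
        uvw = scaled.cell_velocity()
        umag = np.linalg.norm(np.where(scaled.solid[..., None], 0.0, uvw),
                              axis=-1)
        # pore-centre point sample in cell coordinates
        xc_loc = cell.ms.pore_x / 2.0
        yc_loc = cell.ms.pore_y / 2.0
        u_pt = _trilinear(cell.grid, umag, xc_loc, yc_loc, p.z)
        u_ns = near_surface_velocity(cell, scaled, p.height_um,
                                     near_surface_offset)
        tau = beam_averaged_wss(cell, scaled, fluid, p.height_um)
        rows.append({
            "microstructure": p.microstructure, "pore": p.pore,
            "height_um": p.height_um,
            "superficial_um_s": s * 1e6,
            "u_point_um_s": u_pt * 1e6,
            "u_near_surface_um_s": u_ns * 1e6,
            "wss_mPa": tau * 1e3,
        })
    return pd.DataFrame(rows)
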